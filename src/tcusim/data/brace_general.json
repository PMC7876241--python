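{
  "name": "general",
  "curve_form": "quadratic",
  "coefficients": [
    0.0,
    0.0,
    0.0014
  ],
  "plateau_angle_deg": null,
  "r_B_m": 0.2,
  "approximate": true,
  "note": "Synthetic stand-in moment/angle curve: quadratic, gradual at low flexion (~11 N*m at 90 deg). Manufacturer bench calibrations are not public."
}
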