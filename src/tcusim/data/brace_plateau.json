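{
  "name": "plateau",
  "curve_form": "quadratic",
  "coefficients": [
    0.0,
    0.0,
    0.0017
  ],
  "plateau_angle_deg": 100.0,
  "r_B_m": 0.2,
  "approximate": true,
  "note": "Synthetic stand-in moment/angle curve: quadratic rising to ~14 N*m at 90 deg, clamped constant above 100 deg of flexion. Manufacturer bench calibrations are not public."
}
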