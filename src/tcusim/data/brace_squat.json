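{
  "name": "squat",
  "curve_form": "linear",
  "coefficients": [
    0.0,
    0.19,
    0.0
  ],
  "plateau_angle_deg": null,
  "r_B_m": 0.2,
  "approximate": true,
  "note": "Synthetic stand-in moment/angle curve: linear extension-assist reaching ~17 N*m at 90 deg. Manufacturer bench calibrations are not public; do not read absolute braced-force magnitudes off this curve."
}
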