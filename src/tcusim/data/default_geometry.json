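{
  "name": "synthetic-reference-geometry",
  "note": "Synthetic stand-in parameter set for the planar crossed four-bar knee model, at a 0.38 m reference tibia. Values are anatomically plausible magnitudes chosen for solvability over 0-135 deg of flexion and qualitatively realistic kinematics (posterior femoral rollback, extensor mechanism force ratios); they are NOT subject-specific measurements. Replace with measured geometry for any subject-specific work.",
  "reference_tibia_length_m": 0.38,
  "parameters": [
    {"name": "ac_tibia_anterior", "value": 0.022, "unit": "m", "tag": "linear"},
    {"name": "pc_tibia_posterior", "value": 0.0137, "unit": "m", "tag": "linear"},
    {"name": "ac_length", "value": 0.0505, "unit": "m", "tag": "linear"},
    {"name": "pc_length", "value": 0.0326, "unit": "m", "tag": "linear"},
    {"name": "femoral_link_length", "value": 0.0254, "unit": "m", "tag": "linear"},
    {"name": "patellar_tendon_length", "value": 0.0664, "unit": "m", "tag": "linear"},
    {"name": "patella_thickness", "value": 0.0283, "unit": "m", "tag": "linear"},
    {"name": "trochlea_radius", "value": 0.0329, "unit": "m", "tag": "linear"},
    {"name": "trochlea_offset", "value": 0.0151, "unit": "m", "tag": "linear"},
    {"name": "tuberosity_distance", "value": 0.0484, "unit": "m", "tag": "linear"},
    {"name": "hamstring_posterior", "value": 0.0437, "unit": "m", "tag": "linear"},
    {"name": "femoral_link_angle", "value": 303.3, "unit": "deg", "tag": "angular"},
    {"name": "trochlea_angle", "value": 124.8, "unit": "deg", "tag": "angular"},
    {"name": "quadriceps_angle_offset", "value": -6.2, "unit": "deg", "tag": "angular"}
  ]
}
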