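{
  "description": "Default left-hemisphere language-network seed coordinates (MNI mm). These are canonical literature seeds for the classical perisylvian language areas, shipped as substitutable defaults: replace this file to use exact published coordinates from a meta-analysis of choice. x must be negative (left); right-hemisphere homologues are generated by mirroring x -> -x.",
  "rois": [
    {"name": "BA44_pars_opercularis", "x": -52, "y": 12, "z": 12, "radius_mm": 5.0},
    {"name": "BA45_pars_triangularis", "x": -48, "y": 28, "z": 8, "radius_mm": 5.0},
    {"name": "BA22_posterior_STG", "x": -56, "y": -42, "z": 6, "radius_mm": 5.0},
    {"name": "BA39_angular_gyrus", "x": -46, "y": -62, "z": 30, "radius_mm": 5.0},
    {"name": "BA40_supramarginal_gyrus", "x": -54, "y": -44, "z": 26, "radius_mm": 5.0},
    {"name": "MFG_middle_frontal", "x": -42, "y": 24, "z": 28, "radius_mm": 5.0}
  ]
}
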