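[
 {"name": "monodentate", "denticity": 1, "ca_angles": []},
 {"name": "bidentate_cis", "denticity": 2, "ca_angles": [90.0]},
 {"name": "bidentate_trans", "denticity": 2, "ca_angles": [180.0]},
 {"name": "tridentate_fac", "denticity": 3, "ca_angles": [90.0, 90.0, 90.0]},
 {"name": "tridentate_mer", "denticity": 3, "ca_angles": [90.0, 90.0, 180.0]},
 {"name": "tetradentate_planar", "denticity": 4,
  "ca_angles": [90.0, 90.0, 90.0, 90.0, 180.0, 180.0]},
 {"name": "tetradentate_tripodal", "denticity": 4,
  "ca_angles": [85.0, 85.0, 85.0, 118.0, 118.0, 118.0]},
 {"name": "pentadentate_planar", "denticity": 5,
  "ca_angles": [72.0, 72.0, 72.0, 72.0, 72.0,
                144.0, 144.0, 144.0, 144.0, 144.0]},
 {"name": "hexadentate_octahedral", "denticity": 6,
  "ca_angles": [90.0, 90.0, 90.0, 90.0, 90.0, 90.0,
                90.0, 90.0, 90.0, 90.0, 90.0, 90.0,
                180.0, 180.0, 180.0]}
]
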