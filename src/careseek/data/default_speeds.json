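{
  "landcover": {
    "tree_cover_broadleaved": {"code": 1, "speed_kmh": 5, "mode": "WALKING"},
    "tree_cover_needleleaved": {"code": 2, "speed_kmh": 5, "mode": "WALKING"},
    "tree_cover_other": {"code": 3, "speed_kmh": 2, "mode": "WALKING"},
    "shrub": {"code": 4, "speed_kmh": 5, "mode": "WALKING"},
    "herbaceous": {"code": 5, "speed_kmh": 3, "mode": "WALKING"},
    "sparse_herbaceous": {"code": 6, "speed_kmh": 4, "mode": "WALKING"},
    "cultivated": {"code": 7, "speed_kmh": 5, "mode": "WALKING"},
    "bare_desert": {"code": 8, "speed_kmh": 2, "mode": "WALKING"},
    "water": {"code": 9, "speed_kmh": 0, "mode": "NONE"}
  },
  "roads": {
    "primary": {"speed_kmh": 80, "mode": "MOTORIZED"},
    "secondary": {"speed_kmh": 60, "mode": "MOTORIZED"},
    "tertiary": {"speed_kmh": 10, "mode": "CYCLING"}
  },
  "rivers": {"speed_kmh": 0, "mode": "NONE"}
}
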