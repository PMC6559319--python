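{
  "comment": "SYNTHETIC default granule palettes (channels uv, b, g, r; linear reflectance). Invented constants, not measured gravel spectra: the mudflat palette is a low-contrast brown/green pair at 1:1, the rockpool palette spans black-grey-white-purple at equal ratios, musselbed is an intermediate blue-black mix.",
  "mudflat": {
    "granule_palette": [
      {"reflectance": {"uv": 0.05, "b": 0.08, "g": 0.15, "r": 0.25}, "weight": 0.5},
      {"reflectance": {"uv": 0.06, "b": 0.10, "g": 0.25, "r": 0.15}, "weight": 0.5}
    ],
    "granule_size_px": [5, 9],
    "heterogeneity": 0.04
  },
  "rockpool": {
    "granule_palette": [
      {"reflectance": {"uv": 0.02, "b": 0.03, "g": 0.03, "r": 0.03}, "weight": 0.25},
      {"reflectance": {"uv": 0.10, "b": 0.35, "g": 0.35, "r": 0.35}, "weight": 0.25},
      {"reflectance": {"uv": 0.30, "b": 0.80, "g": 0.80, "r": 0.80}, "weight": 0.25},
      {"reflectance": {"uv": 0.15, "b": 0.30, "g": 0.10, "r": 0.25}, "weight": 0.25}
    ],
    "granule_size_px": [5, 9],
    "heterogeneity": 0.04
  },
  "musselbed": {
    "granule_palette": [
      {"reflectance": {"uv": 0.05, "b": 0.20, "g": 0.12, "r": 0.10}, "weight": 0.4},
      {"reflectance": {"uv": 0.03, "b": 0.06, "g": 0.05, "r": 0.05}, "weight": 0.35},
      {"reflectance": {"uv": 0.12, "b": 0.25, "g": 0.22, "r": 0.20}, "weight": 0.25}
    ],
    "granule_size_px": [6, 12],
    "heterogeneity": 0.05
  }
}
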