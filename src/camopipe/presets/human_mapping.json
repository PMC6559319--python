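{
  "name": "human_mapping",
  "comment": "SYNTHETIC placeholder camera-to-cone mapping for the human trichromat (uv, b, g, r camera channels to LW, MW, SW catches). Documented stand-in weights; supply a fitted matrix for real imagery.",
  "receptors": ["lw", "mw", "sw"],
  "channels": ["uv", "b", "g", "r"],
  "matrix": [
    [0.0, 0.05, 0.35, 0.6],
    [0.0, 0.15, 0.65, 0.2],
    [0.2, 0.7, 0.1, 0.0]
  ]
}
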