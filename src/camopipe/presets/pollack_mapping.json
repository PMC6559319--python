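{
  "name": "pollack_mapping",
  "comment": "SYNTHETIC placeholder camera-to-cone mapping for the pollack dichromat. The study's fitted mapping matrices are not published; these documented stand-in weights map normalized camera responses (uv, b, g, r) to LW and SW catches. Supply a fitted matrix for real imagery.",
  "receptors": ["lw", "sw"],
  "channels": ["uv", "b", "g", "r"],
  "matrix": [
    [0.0, 0.0, 0.3, 0.7],
    [0.2, 0.7, 0.1, 0.0]
  ]
}
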