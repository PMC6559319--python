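{
  "name": "human_trichromat",
  "comment": "Human trichromat: explicit per-receptor Weber fractions LW 0.020, MW 0.028, SW 0.066; relative cone abundances LW 0.629, MW 0.214, SW 0.057; achromatic channel LW+MW with Weber fraction 0.1.",
  "names": ["lw", "mw", "sw"],
  "weber_reference": 0.020,
  "abundances": {"lw": 0.629, "mw": 0.214, "sw": 0.057},
  "per_receptor_weber": {"lw": 0.020, "mw": 0.028, "sw": 0.066},
  "luminance_weber": 0.1,
  "achromatic_channels": ["lw", "mw"]
}
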