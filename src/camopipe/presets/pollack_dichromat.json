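{
  "name": "pollack_dichromat",
  "comment": "Pollack (Pollachius pollachius) dichromat: LW + SW. Weber fraction 0.05 for the most abundant cone class, cone ratios LW 339 : SW 168. Luminance channel = LW catch; the luminance Weber fraction is a package default (configurable), not a published value.",
  "names": ["lw", "sw"],
  "weber_reference": 0.05,
  "abundances": {"lw": 339, "sw": 168},
  "luminance_weber": 0.05,
  "achromatic_channels": ["lw"]
}
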