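# camopipe

Quantifying animal camouflage from calibrated imagery: colour and pattern
metrics, receptor-noise-limited discriminability, and visual-search
detection analysis — built around the question of how ontogenetic colour
change alters the background match of shore crabs (*Carcinus maenas*)
reared on contrasting gravel habitats, and how detectable different crab
phenotypes are to searching "predators" in a touch-screen game.

It is written for visual-ecology researchers who need the full chain from
image to discriminability statistic, and ships synthetic-data generators
that emulate the study design (two shade classes reared on mudflat vs rock
pool gravel for 10 weeks; a 30-s-per-slide search game over a 3 × 3 crab
origin × background design) so every stage runs and is testable with no
photographic archive.

## The models

**Receptor-noise-limited (RNL) discrimination.** Stimuli are compared via
quantum catches `q_i` per receptor class. Receptor contrasts are
Weber–Fechner log ratios `Δf_i = ln(q_i^A / q_i^B)`; per-receptor noise is
`e_i = w · sqrt(η_max / η_i)` from the Weber fraction `w` of the most
abundant cone class and relative abundances `η` (or explicit per-receptor
Weber fractions). Discriminability in just-noticeable differences:

    dichromat:   ΔS = |Δf₁ − Δf₂| / sqrt(e₁² + e₂²)
    trichromat:  ΔS² = (e₁²(Δf₃−Δf₂)² + e₂²(Δf₃−Δf₁)² + e₃²(Δf₂−Δf₁)²)
                       / ((e₁e₂)² + (e₁e₃)² + (e₂e₃)²)
    general n:   ΔS² = Σ_{i<j} a_i a_j (Δf_i − Δf_j)² / Σ_i a_i,  a_i = 1/e_i²

with the achromatic channel handled separately as
`ΔS = |ln(lum_A/lum_B)| / w_lum`. ΔS < 1 is effectively indistinguishable,
1–3 uncertain, > 3 reliably discriminable. Presets: a pollack dichromat
(`w = 0.05`, cone ratios LW 339 : SW 168) and a human trichromat (Weber
fractions LW 0.020, MW 0.028, SW 0.066; abundances 0.629/0.214/0.057;
achromatic channel LW+MW with `w_lum = 0.1`).

**Granularity pattern analysis.** The image is decomposed into
octave-spaced spatial-frequency bands (marking sizes 2, 4, …, 2^k px) with
radial raised-cosine filters whose squared transfers partition unity, so
band energies (variance of each band-filtered image over the mask) sum
exactly to the image's non-DC spectral variance. Four summaries: maximum
power (pattern dominance), proportional power (diversity), total power
(overall contrast), mean power.

**Calibration and colour.** Raw images are linearised against 7% / 93%
grey standards (per-channel affine map), region colour is summarised as
mean normalized camera responses with brightness `(R+G+B)/3` and hue
`R/B`, and catches are a linear camera-to-cone mapping of the channel
means. Colour and pattern variable sets are each reduced by PCA
(correlation matrix, sign fixed so the largest loading is positive).

## Worked example

Run the common-garden analysis end to end on the synthetic cohort
(60 crabs: 17 dark-mud, 16 dark-rock, 13 pale-mud, 14 pale-rock,
photographed weekly for 10 weeks):

```bash
python analysis/02_ontogeny_match.py --seed 1
```

```
== background match through ontogeny (fish dichromat JNDs) ==
-- luminance_jnd --
  dark-mudflat   x̄ start-end = 9.58-1.02, SE = 0.10-0.15 (n = 17)
  dark-rockpool  x̄ start-end = 1.72-12.08, SE = 0.33-0.36 (n = 16)
  pale-mudflat   x̄ start-end = 12.08-1.44, SE = 0.09-0.15 (n = 13)
  pale-rockpool  x̄ start-end = 1.39-9.31, SE = 0.21-0.27 (n = 14)
-- chromatic_jnd --
  dark-mudflat   x̄ start-end = 2.65-1.58, SE = 0.13-0.19 (n = 17)
  ...
colour PCA: PC1 explains 88.5% of variance (eigenvalue 4.42); 1 component(s) with eigenvalue > 1
```

Reading this: every synthetic crab darkens and greens with age, so crabs
reared on the dark mudflat gravel *converge* on their background (luminance
JND falls from ~9.6 to ~1.0 — from easily discriminable to the
indistinguishable/uncertain boundary), while crabs on the paler rock-pool
gravel *diverge* (JND rises). The five colour channels collapse onto a
single brightness-dominated principal component, mirroring how strongly
correlated normalized camera responses are in this kind of data.

The detection-game analysis (`python analysis/03_detection_game.py`)
simulates ~80,000 slides and recovers the injected structure: mean search
time 2.08 s on mudflat, 2.46 s on mussel bed and 3.24 s on rock-pool
backgrounds (harder with increasing visual complexity), with dark-green
mudflat-origin crabs the slowest to find (3.05 s) — and scores each crab
origin × background cell with the human-vision RNL model.
`analysis/01_simulate_cohort.py` writes example images of everything the
generators produce. The same steps are available as CLI verbs:
`camopipe synth | calibrate | pattern | jnd | ontogeny | detect`.

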