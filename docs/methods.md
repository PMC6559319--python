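# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and what the test battery does and does not establish.

## Receptor-noise-limited discrimination

The vision module scores the discriminability of two stimuli from their
quantum catches under an observer defined by receptor names, relative cone
abundances and Weber fractions. Receptor contrasts use the natural-log
(Weber–Fechner) form, `Δf_i = ln(q_i^A / q_i^B)` — the standard form for
this model family; a linear-contrast variant would differ only at large
contrasts. Noise per receptor is `e_i = w·sqrt(η_max/η_i)` unless explicit
per-receptor Weber fractions are supplied (the human preset supplies
them; the fish preset derives SW noise from the LW Weber fraction 0.05 and
the 339:168 cone ratio). Assumptions inherited from the model family:
independent noise per channel, opponent processing of all channel pairs,
and intensity information carried by a separate achromatic channel — the
chromatic ΔS is therefore invariant to a common intensity scaling of both
stimuli, and symmetric in the pair.

Closed forms are used for 2 and 3 receptors; any larger receptor set goes
through the general quadratic form `ΔS² = Σ_{i<j} a_i a_j (Δf_i − Δf_j)² /
Σ_i a_i` with `a_i = e_i⁻²`, which reduces algebraically to the closed
forms and is test-enforced to agree with them to 1e-10. This keeps the
module usable for tetrachromatic (e.g. avian) observers.

Choices where the conventions are genuinely open:

* **Achromatic channels.** Human luminance is the LW+MW catch sum with
  Weber fraction 0.1. A fish luminance channel is not standardised; the
  preset uses the LW catch with Weber fraction 0.05, configurable.
* **JND bands.** Boundaries at 1 and 3 JND; both boundary values fall in
  the closed "uncertain" interval.
* **Near-zero catches.** Catches must be positive for log contrasts;
  non-positive mapped catches are floored at 1e-6 with a warning (or made
  a hard error with `floor=None`). The floor only matters for pathological
  mappings; it is flagged whenever applied.
* **Region-level catches.** JNDs compare region-mean catches (one vector
  per crab, one per background region), not pixel-wise distributions.

## Calibration and region colour

Calibration is the per-channel affine map fixed by the 7% and 93% grey
standard means, applied pixelwise and clipped to [0, 1.5] (headroom above
the high standard for specular pixels). Inputs are assumed linear
(RAW-derived); a per-channel transfer-function hook is provided instead of
a built-in linearization curve. Region colour is the masked channel means
plus brightness `(R+G+B)/3` and hue `R/B` (undefined at zero blue). Since
it is ambiguous whether "normalized camera responses" should additionally
be sum-normalized before multivariate analysis, both raw means and
sum-normalized proportions are exposed, labelled distinctly
(`region_proportions`); the pipeline uses raw means. Camera-to-cone
mapping matrices are study-specific fitted objects that are not published;
the shipped `pollack_mapping` and `human_mapping` presets are documented
synthetic placeholders, and all quantitative tests use explicit matrices.

## Granularity analysis

Bands are octave-spaced (2, 4, …, 2^k px marking size) radial filters in
the 2-D Fourier plane. Adjacent bands crossfade with cos/sin quadrature in
log2 frequency so the *squared* amplitude transfers form a partition of
unity at every non-DC frequency; frequencies beyond the outermost band
centres belong wholly to the nearest band and DC is excluded. Band energy
is defined as the variance of the band-filtered image restricted to the
mask, after mean-filling pixels outside the mask (which exactly decouples
the statistic from anything outside the region). Under a full mask the
band energies then sum *exactly* to the image's non-DC spectral variance
(Parseval) — this conservation property is why the partition is taken in
power rather than amplitude, and it is what makes "total power" a true
decomposition of overall contrast. Raised-cosine (not hard-annulus) edges
avoid spatial ringing. The analysis channel defaults to the luminance
plane (mean of visible channels); per-channel spectra and an optional
divide-by-mean normalization are available but off by default. No
rescaling to a standard size is applied; `scale_px_per_mm` is carried so
band scales can be reported in mm.

## PCA and trajectory summaries

`pca_reduce` eigendecomposes the correlation matrix by default (the
colour/pattern variables live on different scales); covariance-matrix PCA
is a flag. Signs are oriented so each component's largest-magnitude
loading is positive, and both the standardization mode and the sign
convention are recorded in run metadata rather than left implicit. The
eigenvalue > 1 retention count is reported, never silently applied.
Trajectory summaries are per shade × background × week cell means with
SE = sd/√n (absent at n = 1), invariant to record order.

## Synthetic-data generators

The generators define the study conditions the pipeline is exercised
under; they are deliberately simple structural emulations, not renderings.

* **Backgrounds** are jittered-grid granule mosaics. The mudflat palette
  is a two-colour brown/green mix at 1:1, rock pool is
  black/grey/white/purple at equal ratios, mussel bed an intermediate
  blue-black mix; all palette reflectances are invented constants (4
  channels: UV, B, G, R) chosen so mudflat is low-contrast and rock pool
  spans dark–light. Granule sides are drawn from a size range per cell;
  each granule takes one weighted palette draw with multiplicative jitter
  (sd = `heterogeneity`). Grid cells rather than Voronoi polygons: the
  statistics under test depend on marking size and contrast, not granule
  shape.
* **Crab series** are elliptical carapace masks (width:height ≈ 1:0.78)
  with zero-mean Gaussian-blob markings applied multiplicatively at a
  configurable contrast. Weekly drift: greening shifts G up by the rate
  and R, B down by half of it (additive); darkening multiplies all
  channels by `(1 − rate)` per week; marking contrast decays by
  `(1 − rate)` per week; optional per-week channel jitter. Darkening is
  *fractional* rather than an additive decrement: an additive decrement
  drives low channels (UV) into clipping and changes chromatic log-ratios
  as a side-effect of pure intensity loss, whereas multiplicative
  darkening is invisible to the chromatic RNL channel — which is the
  behaviour an intensity change should have. With all rates and noise
  zero the series is constant; out-of-range drifts are clipped with a
  warning.
* **Detection logs** are log-normal search times with additive effects on
  log latency (baseline + background + crab origin + interaction),
  per-cell miss probabilities, and censoring at the 30-s limit (a drawn
  time at/over the limit is recorded as a miss). A log-normal family is
  used because search times are positive and right-skewed; the reported
  summaries are means/SDs only, so the family is a modelling choice.
  Within each game the 9 origin × background cells are assigned
  ⌊20/9⌋ slides each with the remainder on distinct random cells
  (randomized block). Displayed crab size is uniform over a configurable
  pixel range, since only "randomized sizes" is specified.

Default rates (darkening 0.05/wk, greening 0.008/wk, pattern decay
0.12/wk, jitter sd 0.005/wk) were set by forward calculation on the
default palettes to reproduce the qualitative ontogeny: all treatments
darken toward a dark-green phenotype, so dark crabs on mudflat converge
(luminance JND ≈ 9.6 → 1.0 over 10 weeks) while pale crabs on rock pool
diverge, and pattern power decays in all treatments. Default detection
effects are the log ratios of the reported per-habitat (2.08/2.47/3.24 s)
and per-origin (3.11/2.45/2.31 s) mean search times, with the baseline
set so the mudflat-background mean lands on 2.08 s after the log-normal
mean correction; miss probability 0.07 matches an overall hit rate of
~93%.

**What passing tests show — and don't.** The synthetic images share the
real data's *statistical* structure (granule scale and contrast,
treatment-level colour trajectories, balanced trial design) but none of
its optical complexity: no illumination gradients, no specularity, no
camera noise, no registration error, no carapace texture. Tests passing
on synthetic data therefore validate the *computations* (calibration
algebra, band-energy conservation, RNL forms, recovery of injected
effects), not the photographic protocol; absolute JND levels on real
imagery additionally depend on fitted cone mappings and real Weber
fractions.

## Problem sizes and determinism

Every generator and pipeline is a pure function of (parameters, seed);
reruns with the same seed produce bit-identical CSVs, and pipeline output
directories are append-only (a non-empty target is an error). The default
cohort is the canonical 17/16/13/14 crabs × 11 weekly images at 48-px
carapace width on 96-px backgrounds; repeated-seed direction-of-change
checks use a 3-crabs-per-treatment cohort at 32/64 px, which preserves
every qualitative property at a fraction of the cost. Detection recovery
uses 2,000 games × 20 slides. Acceptance checks of the recovery kind
compare against analytic truths (e.g. the censored log-normal mean) at
the 2-SE level, evaluated jointly across the nine design cells so that
simultaneous sampling noise is not mistaken for bias.

## Known limitations

* Mixed-model coefficient tables are out of scope by design: the pipeline
  exports tidy per-specimen-week and per-trial tables for external
  LMER/GLMM fitting rather than re-implementing routine mixed-model
  estimation.
* No spatial vision (acuity, viewing distance) and no von Kries
  adaptation; catches come from region means under a single implicit
  illuminant.
* Pattern *match* between crab and background (as opposed to pattern
  description of each) is intentionally not computed.
* UV and visible frames are assumed pre-registered; no image registration
  is provided.
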