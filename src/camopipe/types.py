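"""Core data containers for the camouflage analysis pipeline.

The unit of image analysis is the :class:`ReflectanceImage`: a stack of
linear-reflectance channel planes (typically ``uv, b, g, r``) plus an
optional spatial scale. Region-level colour is summarised as a
:class:`RegionColour` (normalized camera responses: per-channel means plus
the derived brightness ``(R+G+B)/3`` and hue ``R/B``). Observers are
described by a :class:`ReceptorSet` (receptor names, Weber fractions,
relative cone abundances) and a :class:`ReceptorMapping` taking camera
channels to photoreceptor quantum catches.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = [
    "ReflectanceImage",
    "RegionColour",
    "ReceptorSet",
    "ReceptorMapping",
    "DiscriminabilityBand",
    "classify_jnd",
    "GranularitySpectrum",
    "FilterBank",
    "PcaResult",
    "BackgroundStyle",
    "CrabPhenotype",
    "OntogenyParams",
    "DetectionEffects",
]

# Small headroom above the 93% grey standard is legitimate (specular pixels).
REFLECTANCE_CEILING = 1.5


@dataclass
class ReflectanceImage:
    """Multi-channel linear reflectance raster.

    ``pixels`` has shape ``(n_channels, height, width)``; ``channels`` names
    each plane in order. Values are linear reflectance in ``[0, 1.5]``.
    """

    channels: tuple[str, ...]
    pixels: np.ndarray
    scale_px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channels):
            raise DataError(
                f"pixels must be (n_channels, h, w) with n_channels={len(self.channels)}; "
                f"got shape {self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > REFLECTANCE_CEILING:
            raise DataError(
                f"reflectance values outside [0, {REFLECTANCE_CEILING}]: min={lo:g}, max={hi:g}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[self.channels.index(name)]
        except ValueError:
            raise DataError(f"image has no channel {name!r}; channels are {self.channels}")

    def luminance_plane(self) -> np.ndarray:
        """Mean of the visible (b, g, r) planes — default pattern-analysis channel."""
        vis = [c for c in ("b", "g", "r") if c in self.channels]
        if not vis:
            raise DataError("image has no visible (b/g/r) channels")
        return np.mean([self.channel(c) for c in vis], axis=0)


@dataclass(frozen=True)
class RegionColour:
    """Normalized camera responses averaged over a masked region.

    ``brightness`` is the arithmetic mean of the visible channel means,
    ``(R+G+B)/3``; ``hue`` is the red/blue ratio and is ``None`` (undefined)
    when the blue mean is zero.
    """

    brightness: float
    r_mean: float
    g_mean: float
    b_mean: float
    uv_mean: float
    hue: float | None

    @classmethod
    def from_channel_means(cls, r: float, g: float, b: float, uv: float = float("nan")) -> "RegionColour":
        hue = (r / b) if b > 0 else None
        return cls(
            brightness=(r + g + b) / 3.0,
            r_mean=float(r), g_mean=float(g), b_mean=float(b), uv_mean=float(uv),
            hue=hue,
        )

    def channel_vector(self, channels: Sequence[str]) -> np.ndarray:
        lookup = {
            "r": self.r_mean, "g": self.g_mean, "b": self.b_mean,
            "uv": self.uv_mean, "brightness": self.brightness,
        }
        try:
            return np.array([lookup[c] for c in channels], dtype=float)
        except KeyError as exc:
            raise ConfigurationError(f"unknown channel {exc} requested from RegionColour")


@dataclass(frozen=True)
class ReceptorSet:
    """Observer definition for the receptor-noise-limited model.

    When ``per_receptor_weber`` is absent, per-receptor noise is derived from
    the Weber fraction of the most abundant class by the usual abundance
    scaling ``e_i = w * sqrt(eta_max / eta_i)``. Explicit Weber fractions
    override that scaling. ``achromatic_channels`` lists the receptor(s)
    whose summed catch forms the luminance signal.
    """

    names: tuple[str, ...]
    weber_reference: float
    abundances: Mapping[str, float]
    luminance_weber: float
    per_receptor_weber: Mapping[str, float] | None = None
    achromatic_channels: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "achromatic_channels", tuple(self.achromatic_channels))
        if len(self.names) < 2:
            raise ConfigurationError("a ReceptorSet needs at least two receptor classes")
        for n in self.names:
            if n not in self.abundances:
                raise ConfigurationError(f"no abundance given for receptor {n!r}")
            if not self.abundances[n] > 0:
                raise ConfigurationError(f"abundance for receptor {n!r} must be > 0")
        if not self.weber_reference > 0:
            raise ConfigurationError("weber_reference must be > 0")
        if not self.luminance_weber > 0:
            raise ConfigurationError("luminance_weber must be > 0")
        for c in self.achromatic_channels:
            if c not in self.names:
                raise ConfigurationError(f"achromatic channel {c!r} is not a receptor")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReceptorSet":
        return cls(
            names=tuple(d["names"]),
            weber_reference=float(d["weber_reference"]),
            abundances={k: float(v) for k, v in d["abundances"].items()},
            luminance_weber=float(d["luminance_weber"]),
            per_receptor_weber=(
                {k: float(v) for k, v in d["per_receptor_weber"].items()}
                if d.get("per_receptor_weber") else None
            ),
            achromatic_channels=tuple(d.get("achromatic_channels", ())),
            name=d.get("name", ""),
        )

    @classmethod
    def from_json(cls, path) -> "ReceptorSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ReceptorMapping:
    """Linear map from camera channel means to receptor quantum catches."""

    receptors: tuple[str, ...]
    channels: tuple[str, ...]
    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptors", tuple(self.receptors))
        object.__setattr__(self, "channels", tuple(self.channels))
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.receptors), len(self.channels)):
            raise ConfigurationError(
                f"mapping matrix must be {len(self.receptors)}x{len(self.channels)}; got {m.shape}"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReceptorMapping":
        return cls(
            receptors=tuple(d["receptors"]),
            channels=tuple(d["channels"]),
            matrix=np.asarray(d["matrix"], dtype=float),
            name=d.get("name", ""),
        )

    @classmethod
    def from_json(cls, path) -> "ReceptorMapping":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def classify_jnd(jnd: float) -> str:
    """Discriminability band for a ΔS value.

    Below 1 JND two stimuli are effectively indistinguishable; the closed
    interval [1, 3] is treated as a region of uncertain discrimination;
    above 3 the stimuli are reliably discriminable.
    """
    if jnd < 0:
        raise DataError("jnd must be non-negative")
    if jnd < 1.0:
        return "indistinguishable"
    if jnd <= 3.0:
        return "uncertain"
    return "discriminable"


@dataclass(frozen=True)
class DiscriminabilityBand:
    jnd: float
    band: str

    @classmethod
    def from_jnd(cls, jnd: float) -> "DiscriminabilityBand":
        return cls(jnd=float(jnd), band=classify_jnd(float(jnd)))


@dataclass(frozen=True)
class FilterBank:
    """Octave-spaced radial band-pass bank in the 2-D Fourier plane.

    ``transfers`` holds one amplitude transfer function per band, shape
    ``(n_bands, h, w)`` on the unshifted FFT grid. The squared transfers form
    a partition of unity at every non-DC frequency, so band energies add up
    to the image's non-DC spectral variance (Parseval).
    """

    band_scales_px: tuple[int, ...]
    transfers: np.ndarray
    image_shape: tuple[int, int]

    @property
    def n_bands(self) -> int:
        return len(self.band_scales_px)

    def power_weights(self) -> np.ndarray:
        return self.transfers ** 2


@dataclass(frozen=True)
class GranularitySpectrum:
    """Per-band pattern energy and its four summary statistics."""

    band_scales_px: tuple[int, ...]
    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) != len(self.band_scales_px):
            raise DataError("energies must be one value per band")
        if np.any(e < 0):
            raise DataError("band energies must be non-negative")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "band_scales_px", tuple(self.band_scales_px))

    @property
    def max_power(self) -> float:
        """Pattern dominance: energy at the peak band."""
        return float(self.energies.max())

    @property
    def total_power(self) -> float:
        """Overall pattern contrast: energy summed across all scales."""
        return float(self.energies.sum())

    @property
    def mean_power(self) -> float:
        """Average contrast across the spectrum."""
        return float(self.energies.mean())

    @property
    def proportional_power(self) -> float:
        """Pattern diversity: peak energy over summed energy (nan if no energy)."""
        tot = self.total_power
        return float(self.max_power / tot) if tot > 0 else float("nan")

    @property
    def peak_scale_px(self) -> int:
        return self.band_scales_px[int(np.argmax(self.energies))]


@dataclass(frozen=True)
class PcaResult:
    """Eigendecomposition summary of a records-by-variables table."""

    variables: tuple[str, ...]
    loadings: np.ndarray          # variables x components, orthonormal columns
    scores: np.ndarray            # records x components
    eigenvalues: np.ndarray       # descending
    variance_explained: np.ndarray  # fractions, descending
    standardized: bool
    n_retained_kaiser: int        # eigenvalue > 1 rule, reported not applied


# ---------------------------------------------------------------------------
# Synthetic-generator parameter types
# ---------------------------------------------------------------------------

IMAGE_CHANNELS = ("uv", "b", "g", "r")


@dataclass(frozen=True)
class BackgroundStyle:
    """Gravel-background recipe: a granule palette plus placement geometry.

    The mudflat style is a two-entry brown/green palette at equal weight;
    the rockpool style has four entries (black/grey/white/purple) at equal
    weight. ``heterogeneity`` scales per-granule multiplicative reflectance
    jitter (0 = every granule exactly its palette colour).
    """

    name: str
    granule_palette: tuple[tuple[np.ndarray, float], ...]  # (reflectance uv,b,g,r; weight)
    granule_size_px: tuple[int, int]
    heterogeneity: float

    def __post_init__(self) -> None:
        pal = tuple(
            (np.asarray(refl, dtype=float), float(w)) for refl, w in self.granule_palette
        )
        object.__setattr__(self, "granule_palette", pal)
        weights = np.array([w for _, w in pal])
        if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError("granule palette mixing weights must sum to 1")
        for refl, _ in pal:
            if refl.shape != (len(IMAGE_CHANNELS),):
                raise ConfigurationError("palette reflectance vectors must have 4 channels (uv,b,g,r)")
            if refl.min() < 0 or refl.max() > 1:
                raise ConfigurationError("palette reflectances must lie in [0, 1]")
        lo, hi = self.granule_size_px
        if not (0 < lo <= hi):
            raise ConfigurationError("granule_size_px must be a positive (lo, hi) range")
        if self.heterogeneity < 0:
            raise ConfigurationError("heterogeneity must be non-negative")
        if self.name == "mudflat":
            if len(pal) != 2 or not np.allclose(weights, 0.5):
                raise ConfigurationError("mudflat palette must have exactly 2 entries at equal weight")
        if self.name == "rockpool":
            if len(pal) != 4 or not np.allclose(weights, 0.25):
                raise ConfigurationError("rockpool palette must have exactly 4 entries at equal weight")


@dataclass(frozen=True)
class CrabPhenotype:
    """Starting carapace phenotype of one simulated crab."""

    base_reflectance: np.ndarray   # per-channel (uv, b, g, r) in [0, 1]
    pattern_contrast: float        # relative (multiplicative) marking contrast
    marking_size_px: int
    shade_class: str               # "pale" | "dark"
    carapace_width_px: int

    def __post_init__(self) -> None:
        base = np.asarray(self.base_reflectance, dtype=float)
        object.__setattr__(self, "base_reflectance", base)
        if base.shape != (len(IMAGE_CHANNELS),):
            raise ConfigurationError("base_reflectance must have 4 channels (uv,b,g,r)")
        if base.min() < 0 or base.max() > 1:
            raise ConfigurationError("base_reflectance must lie in [0, 1]")
        if self.shade_class not in ("pale", "dark"):
            raise ConfigurationError("shade_class must be 'pale' or 'dark'")
        if self.pattern_contrast < 0:
            raise ConfigurationError("pattern_contrast must be non-negative")
        if self.marking_size_px < 1 or self.carapace_width_px < 1:
            raise ConfigurationError("marking_size_px and carapace_width_px must be positive")


@dataclass(frozen=True)
class OntogenyParams:
    """Weekly drift of a crab phenotype.

    ``darkening_rate`` is a per-week *fractional* brightness decrease (all
    channels are multiplied by ``(1 - rate)`` each week), so darkening is a
    pure intensity change that leaves chromatic log-ratios untouched.
    ``greening_rate`` shifts the G channel up by that amount per week while
    R and B each drop by half of it. ``pattern_decay_rate`` multiplies the
    marking contrast by ``(1 - rate)`` per week. With all rates and
    ``noise_sd`` zero the phenotype is constant across weeks.
    """

    weeks: int = 10
    darkening_rate: float = 0.0
    greening_rate: float = 0.0
    pattern_decay_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.weeks < 1:
            raise ConfigurationError("weeks must be >= 1")
        if not (0 <= self.darkening_rate < 1):
            raise ConfigurationError("darkening_rate must be in [0, 1)")
        if not (0 <= self.pattern_decay_rate <= 1):
            raise ConfigurationError("pattern_decay_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


HABITATS = ("mudflat", "musselbed", "rockpool")


@dataclass(frozen=True)
class DetectionEffects:
    """Additive structure on log latency for the detection-game generator.

    Hit latencies are log-normal: ``log L = baseline + background effect +
    crab-origin effect + interaction + N(0, latency_sd_log)``. Each cell also
    has a miss probability; in addition any drawn latency at or above
    ``time_limit_s`` is recorded as a miss (censored search).
    """

    baseline_log_latency: float = 0.0
    background_effects: Mapping[str, float] = field(default_factory=dict)
    crab_origin_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_terms: Mapping[tuple[str, str], float] = field(default_factory=dict)
    miss_probability: float | Mapping[tuple[str, str], float] = 0.0
    latency_sd_log: float = 0.75
    time_limit_s: float = 30.0

    def __post_init__(self) -> None:
        if self.time_limit_s <= 0:
            raise ConfigurationError("time_limit_s must be positive")
        if self.latency_sd_log < 0:
            raise ConfigurationError("latency_sd_log must be non-negative")
        for origin in HABITATS:
            for bg in HABITATS:
                p = self.cell_miss_probability(origin, bg)
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(
                        f"miss probability for cell ({origin}, {bg}) must be in [0, 1]; got {p}"
                    )

    def cell_log_mean(self, origin: str, background: str) -> float:
        return (
            self.baseline_log_latency
            + self.background_effects.get(background, 0.0)
            + self.crab_origin_effects.get(origin, 0.0)
            + self.interaction_terms.get((origin, background), 0.0)
        )

    def cell_miss_probability(self, origin: str, background: str) -> float:
        if isinstance(self.miss_probability, Mapping):
            return float(self.miss_probability.get((origin, background), 0.0))
        return float(self.miss_probability)
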