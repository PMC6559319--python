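"""Synthetic imagery and trial logs with the statistical structure the
analysis assumes.

Three generators, each a pure function of (parameters, seed):

* :func:`generate_background` — gravel-like backgrounds as a jittered grid
  of granules drawn from a habitat palette (mudflat: brown/green 1:1;
  rockpool: black/grey/white/purple equal ratios).
* :func:`generate_crab_series` — weekly masked elliptical "carapace" images
  whose brightness, hue and marking contrast drift at configurable rates,
  emulating ontogenetic darkening/greening and pattern loss.
* :func:`generate_detection_log` — touch-screen search-game trials with
  log-normal latencies, additive effects on log latency, per-cell miss
  probabilities, and censoring at the 30-s time limit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import (
    BackgroundStyle,
    CrabPhenotype,
    DetectionEffects,
    HABITATS,
    IMAGE_CHANNELS,
    OntogenyParams,
    ReflectanceImage,
)

__all__ = [
    "generate_background",
    "generate_crab_series",
    "generate_detection_log",
    "DETECTION_LOG_COLUMNS",
]


def _jittered_edges(total: int, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    """Cut [0, total) into runs of random length in [lo, hi] (jittered grid lines)."""
    edges = [0]
    while edges[-1] < total:
        edges.append(edges[-1] + int(rng.integers(lo, hi + 1)))
    edges[-1] = total
    return np.array(edges)


def generate_background(
    style: BackgroundStyle, width_px: int, height_px: int, seed: int
) -> ReflectanceImage:
    """Tile an image with randomly placed granules drawn from the palette.

    Granules are the cells of a row/column-jittered grid (cell sides drawn
    from ``granule_size_px``); each granule takes one weighted palette draw
    with multiplicative reflectance jitter of sd ``heterogeneity``, clipped
    to [0, 1]. Deterministic for a fixed seed.
    """
    if width_px < 64 or height_px < 64:
        raise ConfigurationError("background images must be at least 64x64 px")
    rng = np.random.default_rng(seed)
    lo, hi = style.granule_size_px
    y_edges = _jittered_edges(height_px, lo, hi, rng)
    x_edges = _jittered_edges(width_px, lo, hi, rng)
    colours = np.stack([refl for refl, _ in style.granule_palette])
    weights = np.array([w for _, w in style.granule_palette])

    n_cells = (len(y_edges) - 1) * (len(x_edges) - 1)
    draws = rng.choice(len(colours), size=n_cells, p=weights)
    jitter = 1.0 + style.heterogeneity * rng.standard_normal(n_cells)

    pixels = np.empty((len(IMAGE_CHANNELS), height_px, width_px))
    cell = 0
    for y0, y1 in zip(y_edges[:-1], y_edges[1:]):
        for x0, x1 in zip(x_edges[:-1], x_edges[1:]):
            granule = np.clip(colours[draws[cell]] * jitter[cell], 0.0, 1.0)
            pixels[:, y0:y1, x0:x1] = granule[:, None, None]
            cell += 1
    return ReflectanceImage(channels=IMAGE_CHANNELS, pixels=pixels)


def _ellipse_mask(h: int, w: int, width_px: int) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = width_px / 2.0            # semi-axis across the carapace
    b = 0.78 * a                  # carapaces are wider than long
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _spot_field(mask: np.ndarray, marking_size_px: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-sd (over the mask) field of Gaussian blob markings."""
    h, w = mask.shape
    n_spots = max(6, int(mask.sum() / (marking_size_px ** 2 * 4)))
    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, len(ys), size=n_spots)
    signs = rng.choice([-1.0, 1.0], size=n_spots)
    sigma = marking_size_px / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    field = np.zeros((h, w))
    for k in range(n_spots):
        field += signs[k] * np.exp(
            -((yy - ys[idx[k]]) ** 2 + (xx - xs[idx[k]]) ** 2) / (2 * sigma ** 2)
        )
    inside = field[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros_like(field)
    return (field - inside.mean()) / sd


def generate_crab_series(
    phenotype: CrabPhenotype, params: OntogenyParams, seed: int
) -> list[tuple[int, ReflectanceImage, np.ndarray]]:
    """Weekly masked carapace images, weeks 0 … ``params.weeks`` inclusive.

    Week 0 realizes the input phenotype exactly (up to marking rendering).
    Each subsequent week applies the greening shift additively (G up by the
    rate, R and B down by half of it), then the fractional darkening to all
    channels, then per-channel Gaussian jitter of sd ``noise_sd``. Marking
    contrast is multiplicative on the base reflectance and decays by
    ``pattern_decay_rate`` per week. Reflectances that drift outside [0, 1]
    are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    canvas = int(np.ceil(phenotype.carapace_width_px * 1.4))
    mask = _ellipse_mask(canvas, canvas, phenotype.carapace_width_px)
    field = _spot_field(mask, phenotype.marking_size_px, rng)

    g_idx = IMAGE_CHANNELS.index("g")
    r_idx = IMAGE_CHANNELS.index("r")
    b_idx = IMAGE_CHANNELS.index("b")

    series = []
    clipped = False
    for week in range(params.weeks + 1):
        base = phenotype.base_reflectance.copy()
        base[g_idx] += params.greening_rate * week
        base[r_idx] -= params.greening_rate * week / 2.0
        base[b_idx] -= params.greening_rate * week / 2.0
        base *= (1.0 - params.darkening_rate) ** week
        if params.noise_sd > 0:
            base = base + rng.normal(0.0, params.noise_sd, size=base.shape)
        if base.min() < 0 or base.max() > 1:
            clipped = True
            base = np.clip(base, 0.0, 1.0)

        contrast = phenotype.pattern_contrast * (1.0 - params.pattern_decay_rate) ** week
        pixels = np.empty((len(IMAGE_CHANNELS), canvas, canvas))
        for c in range(len(IMAGE_CHANNELS)):
            plane = base[c] * (1.0 + field * contrast)
            pixels[c] = np.where(mask, plane, 0.5)
        if pixels.min() < 0 or pixels.max() > 1:
            clipped = True
            pixels = np.clip(pixels, 0.0, 1.0)
        series.append((week, ReflectanceImage(channels=IMAGE_CHANNELS, pixels=pixels), mask))
    if clipped:
        warnings.warn(
            "ontogeny rates drove reflectance outside [0, 1]; values were clipped",
            stacklevel=2,
        )
    return series


DETECTION_LOG_COLUMNS = [
    "game_id", "player_age_band", "first_play", "vision_mode",
    "crab_origin", "background_habitat", "crab_size_px", "latency_ms", "hit",
]

_AGE_BANDS = ("<10", "10-15", "16-35", "36-50", ">50")


def generate_detection_log(
    effects: DetectionEffects,
    n_games: int,
    slides_per_game: int = 20,
    seed: int = 0,
    crab_size_px: tuple[int, int] = (40, 120),
    first_play_rate: float = 0.7,
) -> pd.DataFrame:
    """Simulated search-game log, one row per slide.

    Within each game the origin × background cells are assigned in a
    balanced randomized block: every cell gets ``slides_per_game // 9``
    slides and the remainder goes to distinct randomly chosen cells. Hit
    latencies are log-normal with the additive structure of ``effects`` on
    log latency; a slide is a miss with its cell's miss probability, or when
    the drawn search time reaches the time limit (censored). Misses carry no
    latency. The slide size range is configurable because the study only
    states that displayed crabs were of randomized sizes.
    """
    if n_games < 1:
        raise ConfigurationError("n_games must be >= 1")
    if slides_per_game < 1:
        raise ConfigurationError("slides_per_game must be >= 1")
    rng = np.random.default_rng(seed)
    cells = [(o, b) for o in HABITATS for b in HABITATS]
    per_cell, remainder = divmod(slides_per_game, len(cells))

    rows = []
    limit_ms = effects.time_limit_s * 1000.0
    for game in range(n_games):
        game_id = f"g{game + 1:06d}"
        age_band = _AGE_BANDS[rng.integers(0, len(_AGE_BANDS))]
        first = bool(rng.random() < first_play_rate)
        vision = "dichromat" if rng.random() < 0.5 else "trichromat"
        assignment = cells * per_cell + [
            cells[i] for i in rng.choice(len(cells), size=remainder, replace=False)
        ]
        rng.shuffle(assignment)
        for origin, background in assignment:
            size = int(rng.integers(crab_size_px[0], crab_size_px[1] + 1))
            miss_p = effects.cell_miss_probability(origin, background)
            latency_ms: float | None
            if rng.random() < miss_p:
                hit = False
                latency_ms = None
            else:
                log_lat = effects.cell_log_mean(origin, background) + (
                    effects.latency_sd_log * rng.standard_normal()
                )
                latency_ms = float(np.round(np.exp(log_lat) * 1000.0))
                if latency_ms >= limit_ms:
                    hit = False           # ran out of time: censored at the limit
                    latency_ms = None
                else:
                    hit = True
            rows.append(
                (game_id, age_band, first, vision, origin, background, size, latency_ms, hit)
            )
    df = pd.DataFrame(rows, columns=DETECTION_LOG_COLUMNS)
    df["latency_ms"] = df["latency_ms"].astype("Int64")
    return df
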