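"""Grey-standard calibration and region colour extraction.

Raw camera responses are mapped to linear reflectance per channel by the
affine transform fixed by two grey standards that reflect 7% and 93% of
light equally across the working spectrum. Region colour is summarised as
mean normalized responses over a binary mask, with brightness ``(R+G+B)/3``
and hue ``R/B`` derived per the study conventions; quantum catches are then
a linear mapping of the channel means.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from .errors import CalibrationError, DataError
from .types import ReceptorMapping, ReflectanceImage, RegionColour

__all__ = [
    "calibrate",
    "extract_region",
    "region_proportions",
    "to_cone_catches",
    "CATCH_FLOOR",
]

# Non-positive catches break the log-ratio contrasts downstream; they are
# floored here with a warning rather than silently propagated.
CATCH_FLOOR = 1e-6


def _region_mask(region, shape: tuple[int, int]) -> np.ndarray:
    """Accept a boolean mask or a (y0, y1, x0, x1) rectangle."""
    if isinstance(region, (tuple, list)) and len(region) == 4:
        y0, y1, x0, x1 = region
        mask = np.zeros(shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != shape:
            raise DataError(f"mask shape {mask.shape} does not match image shape {shape}")
    if not mask.any():
        raise DataError("standard/region mask is empty")
    return mask


def calibrate(
    raw: np.ndarray,
    channels: Sequence[str],
    standard_low,
    standard_high,
    low_value: float = 0.07,
    high_value: float = 0.93,
    scale_px_per_mm: float | None = None,
    linearization: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ReflectanceImage:
    """Affine reflectance calibration against two grey standards.

    Per channel, the mean raw response over the low-standard region is
    mapped to ``low_value`` (default 0.07) and the high-standard mean to
    ``high_value`` (default 0.93); the same affine map is applied pixelwise.
    Inputs are assumed linear (RAW-derived); ``linearization`` optionally
    applies a user-supplied per-channel transfer function first. Output is
    clipped to [0, 1.5] (headroom above the 93% standard for specularities).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[0] != len(channels):
        raise DataError(
            f"raw must be (n_channels, h, w) with n_channels={len(channels)}; got {raw.shape}"
        )
    if linearization is not None:
        raw = np.stack([linearization(plane) for plane in raw])
    low_mask = _region_mask(standard_low, raw.shape[1:])
    high_mask = _region_mask(standard_high, raw.shape[1:])

    out = np.empty_like(raw)
    for i, name in enumerate(channels):
        ml = raw[i][low_mask].mean()
        mh = raw[i][high_mask].mean()
        if mh <= ml:
            raise CalibrationError(
                f"channel {name!r}: high-standard mean ({mh:g}) must exceed "
                f"low-standard mean ({ml:g}); standards inverted or saturated"
            )
        gain = (high_value - low_value) / (mh - ml)
        out[i] = low_value + gain * (raw[i] - ml)
    out = np.clip(out, 0.0, 1.5)
    return ReflectanceImage(channels=tuple(channels), pixels=out, scale_px_per_mm=scale_px_per_mm)


def extract_region(image: ReflectanceImage, mask: np.ndarray) -> RegionColour:
    """Mean normalized responses over a masked region.

    Requires the visible b, g, r channels; uv is optional (NaN when absent).
    Hue (R/B) is returned as ``None`` when the blue mean is zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise DataError(f"mask shape {mask.shape} does not match image shape {image.shape}")
    if not mask.any():
        raise DataError("region mask is empty")
    means = {c: float(image.channel(c)[mask].mean()) for c in image.channels}
    for needed in ("r", "g", "b"):
        if needed not in means:
            raise DataError(f"extract_region requires channel {needed!r}")
    return RegionColour.from_channel_means(
        r=means["r"], g=means["g"], b=means["b"], uv=means.get("uv", float("nan")),
    )


def region_proportions(region: RegionColour, include_uv: bool = True) -> dict[str, float]:
    """Sum-normalized channel proportions (chromatic normalization).

    Whether the study's "normalized camera responses" are raw channel means
    or sum-normalized proportions is a modelling choice; both are exposed
    and labelled distinctly — this is the proportion variant.
    """
    parts = {"r": region.r_mean, "g": region.g_mean, "b": region.b_mean}
    if include_uv and np.isfinite(region.uv_mean):
        parts["uv"] = region.uv_mean
    total = sum(parts.values())
    if total <= 0:
        raise DataError("cannot sum-normalize a region with non-positive total response")
    return {f"{k}_prop": v / total for k, v in parts.items()}


def to_cone_catches(region, mapping: ReceptorMapping, floor: float = CATCH_FLOOR) -> dict[str, float]:
    """Quantum catches ``q = M · channel means``, named per receptor.

    ``region`` is a :class:`RegionColour` or a plain vector ordered as
    ``mapping.channels``. Catches must be strictly positive for the
    log-ratio contrasts; non-positive results are floored at ``floor``
    with a warning (pass ``floor=None`` to make them a hard error).
    """
    if isinstance(region, RegionColour):
        vec = region.channel_vector(mapping.channels)
    else:
        vec = np.asarray(region, dtype=float)
        if vec.shape != (len(mapping.channels),):
            raise DataError(
                f"channel vector must have {len(mapping.channels)} entries "
                f"ordered as {mapping.channels}"
            )
    q = mapping.matrix @ vec
    if np.any(q <= 0):
        bad = [mapping.receptors[i] for i in np.flatnonzero(q <= 0)]
        if floor is None:
            raise DataError(
                f"non-positive quantum catch for receptor(s) {bad}; "
                f"pass a floor value to clip instead"
            )
        warnings.warn(
            f"non-positive quantum catch for receptor(s) {bad}; floored at {floor:g}",
            stacklevel=2,
        )
        q = np.maximum(q, floor)
    return dict(zip(mapping.receptors, q.astype(float)))
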