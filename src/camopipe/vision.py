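"""Receptor-noise-limited (RNL) colour and luminance discrimination.

Discriminability between two stimuli A and B is expressed in just noticeable
differences (JNDs). Receptor contrasts are Weber–Fechner log ratios,
``Δf_i = ln(qA_i / qB_i)`` for quantum catches ``q``; per-receptor noise
``e_i`` comes from the Weber fraction of the most abundant cone class scaled
by relative cone abundance (or from explicit per-receptor Weber fractions).

For a dichromat::

    ΔS = |Δf_1 − Δf_2| / sqrt(e_1² + e_2²)

for a trichromat::

    ΔS² = (e_1²(Δf_3−Δf_2)² + e_2²(Δf_3−Δf_1)² + e_3²(Δf_2−Δf_1)²)
          / ((e_1e_2)² + (e_1e_3)² + (e_2e_3)²)

and for any number of receptors the general quadratic form (with
``a_i = 1/e_i²``)::

    ΔS² = Σ_{i<j} a_i a_j (Δf_i − Δf_j)² / Σ_i a_i

which reduces exactly to the closed forms at n = 2 and n = 3. The achromatic
channel is treated separately: ``ΔS = |ln(lumA/lumB)| / w_lum``.

Because ΔS depends on catches only through log ratios, the chromatic model
is symmetric in (A, B) and invariant to a common intensity scaling of both
stimuli.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .calibration import to_cone_catches
from .errors import DataError
from .types import (
    DiscriminabilityBand,
    ReceptorMapping,
    ReceptorSet,
    RegionColour,
)

__all__ = [
    "receptor_noise",
    "chromatic_jnd",
    "chromatic_jnd_general",
    "achromatic_jnd",
    "luminance_from_catches",
    "match_trajectory",
]


def receptor_noise(receptors: ReceptorSet) -> np.ndarray:
    """Per-receptor noise ``e_i``, ordered as ``receptors.names``.

    With explicit ``per_receptor_weber`` those values are used directly;
    otherwise ``e_i = w · sqrt(η_max / η_i)`` so the most abundant class has
    exactly the reference Weber fraction.
    """
    if receptors.per_receptor_weber is not None:
        return np.array([receptors.per_receptor_weber[n] for n in receptors.names], dtype=float)
    eta = np.array([receptors.abundances[n] for n in receptors.names], dtype=float)
    return receptors.weber_reference * np.sqrt(eta.max() / eta)


def _as_positive_catches(q, n: int, label: str) -> np.ndarray:
    arr = np.asarray(q, dtype=float)
    if arr.shape != (n,):
        raise DataError(f"{label} must have {n} entries (one per receptor); got shape {arr.shape}")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise DataError(f"{label} must contain strictly positive finite catches")
    return arr


def _quadratic_delta_s(df: np.ndarray, e: np.ndarray) -> float:
    a = 1.0 / e ** 2
    i, j = np.triu_indices(len(df), k=1)
    num = float(np.sum(a[i] * a[j] * (df[i] - df[j]) ** 2))
    return float(np.sqrt(num / a.sum()))


def chromatic_jnd_general(qA, qB, receptors: ReceptorSet) -> float:
    """ΔS by the general n-receptor quadratic form (any n ≥ 2)."""
    n = len(receptors.names)
    qa = _as_positive_catches(qA, n, "qA")
    qb = _as_positive_catches(qB, n, "qB")
    df = np.log(qa / qb)
    return _quadratic_delta_s(df, receptor_noise(receptors))


def chromatic_jnd(qA, qB, receptors: ReceptorSet) -> DiscriminabilityBand:
    """Chromatic ΔS between catch vectors, with its discriminability band.

    Uses the dichromat/trichromat closed forms for n = 2 and n = 3 and the
    general quadratic form beyond.
    """
    n = len(receptors.names)
    qa = _as_positive_catches(qA, n, "qA")
    qb = _as_positive_catches(qB, n, "qB")
    df = np.log(qa / qb)
    e = receptor_noise(receptors)
    if n == 2:
        ds = abs(df[0] - df[1]) / np.hypot(e[0], e[1])
    elif n == 3:
        num = (
            e[0] ** 2 * (df[2] - df[1]) ** 2
            + e[1] ** 2 * (df[2] - df[0]) ** 2
            + e[2] ** 2 * (df[1] - df[0]) ** 2
        )
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        ds = np.sqrt(num / den)
    else:
        ds = _quadratic_delta_s(df, e)
    return DiscriminabilityBand.from_jnd(float(ds))


def achromatic_jnd(lumA: float, lumB: float, receptors: ReceptorSet) -> DiscriminabilityBand:
    """Luminance ΔS = |ln(lumA / lumB)| / w_lum."""
    if not (lumA > 0 and lumB > 0):
        raise DataError("luminance signals must be strictly positive")
    ds = abs(np.log(lumA / lumB)) / receptors.luminance_weber
    return DiscriminabilityBand.from_jnd(float(ds))


def luminance_from_catches(catches: dict[str, float], receptors: ReceptorSet) -> float:
    """Achromatic signal: summed catch of the observer's achromatic channels."""
    if not receptors.achromatic_channels:
        raise DataError(f"receptor set {receptors.name or '?'} defines no achromatic channels")
    return float(sum(catches[c] for c in receptors.achromatic_channels))


def match_trajectory(
    records: Iterable[tuple[str, int, RegionColour, RegionColour]],
    receptors: ReceptorSet,
    mapping: ReceptorMapping,
) -> pd.DataFrame:
    """Weekly crab-vs-own-background discriminability table.

    ``records`` yields ``(specimen_id, week, crab_colour, background_colour)``
    for whatever weeks were actually measured; missing weeks are simply
    absent rows, never interpolated. Both members of each pair must come
    from the same calibration and the same camera-to-receptor mapping.

    Returns columns ``specimen_id, week, observer, chromatic_jnd,
    luminance_jnd, chromatic_band, luminance_band``.
    """
    rows = []
    for specimen_id, week, crab, background in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # floor warnings surface once per run elsewhere
            q_crab = to_cone_catches(crab, mapping)
            q_bg = to_cone_catches(background, mapping)
        qc = np.array([q_crab[r] for r in receptors.names])
        qb = np.array([q_bg[r] for r in receptors.names])
        chrom = chromatic_jnd(qc, qb, receptors)
        lum = achromatic_jnd(
            luminance_from_catches(q_crab, receptors),
            luminance_from_catches(q_bg, receptors),
            receptors,
        )
        rows.append(
            {
                "specimen_id": specimen_id,
                "week": int(week),
                "observer": receptors.name or "+".join(receptors.names),
                "chromatic_jnd": chrom.jnd,
                "luminance_jnd": lum.jnd,
                "chromatic_band": chrom.band,
                "luminance_band": lum.band,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "week", "observer",
            "chromatic_jnd", "luminance_jnd", "chromatic_band", "luminance_band",
        ],
    )
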