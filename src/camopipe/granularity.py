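"""Granularity ("pattern energy") analysis.

An image is decomposed into octave-spaced spatial-frequency bands
("granularity bands", labelled by marking size in px) with radial
raised-cosine band-pass filters in the 2-D Fourier plane. The *squared*
amplitude transfers form a partition of unity at every non-DC frequency, so
the per-band energies — the variance of each band-filtered image over the
analysis mask — sum exactly to the image's non-DC spectral variance
(Parseval) under a full mask.

Four summary statistics describe the spectrum: maximum power (pattern
dominance), proportional power (pattern diversity, peak over summed
energy), total power (overall contrast) and mean power (average contrast
across scales).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .types import FilterBank, GranularitySpectrum, ReflectanceImage

__all__ = ["build_bands", "granularity_spectrum", "pattern_table"]


def build_bands(image_shape: tuple[int, int], n_bands: int) -> FilterBank:
    """Octave-spaced radial band bank for ``image_shape``.

    Band scales are 2, 4, …, 2**n_bands px. Adjacent bands are blended with
    a cos/sin quadrature crossfade in log2 spatial frequency (squares sum to
    one); frequencies beyond the outermost band centres are assigned wholly
    to the nearest band, and DC is excluded from every band.
    """
    if n_bands < 2:
        raise ConfigurationError("n_bands must be >= 2")
    h, w = image_shape
    if min(h, w) < 2 ** n_bands:
        feasible = int(np.floor(np.log2(min(h, w))))
        raise ConfigurationError(
            f"image {image_shape} too small for {n_bands} octave bands; "
            f"max feasible n_bands is {feasible}"
        )
    scales = tuple(int(2 ** k) for k in range(1, n_bands + 1))

    fy = np.fft.fftfreq(h)
    fx = np.fft.fftfreq(w)
    r = np.hypot(fy[:, None], fx[None, :])
    nonzero = r > 0
    # u = log2(1/f): band centres sit at u = 1, 2, ..., n_bands (scale 2^u px)
    u = np.zeros_like(r)
    u[nonzero] = -np.log2(r[nonzero])
    pos = np.clip(u, 1.0, float(n_bands)) - 1.0          # in [0, n_bands - 1]
    j0 = np.minimum(pos.astype(int), n_bands - 2)         # lower band of each crossfade
    t = pos - j0                                          # in [0, 1]

    transfers = np.zeros((n_bands, h, w))
    for j in range(n_bands - 1):
        sel = nonzero & (j0 == j)
        transfers[j][sel] += np.cos(0.5 * np.pi * t[sel])
        transfers[j + 1][sel] += np.sin(0.5 * np.pi * t[sel])
    return FilterBank(band_scales_px=scales, transfers=transfers, image_shape=(h, w))


def granularity_spectrum(
    image_channel: np.ndarray,
    mask: np.ndarray,
    bank: FilterBank,
    normalize_by_mean: bool = False,
) -> GranularitySpectrum:
    """Masked band-pass decomposition of a single channel plane.

    Pixels outside the mask are replaced by the masked mean before the FFT,
    decoupling the analysis from anything outside the region. Each band's
    energy is the variance of the band-filtered image restricted to the
    mask. ``normalize_by_mean`` optionally divides the plane by its masked
    mean first (off by default).
    """
    img = np.asarray(image_channel, dtype=float)
    if img.ndim != 2:
        raise DataError("granularity analysis expects a single 2-D channel plane")
    if img.shape != bank.image_shape:
        raise DataError(f"image shape {img.shape} does not match bank shape {bank.image_shape}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise DataError(f"mask shape {mask.shape} does not match image shape {img.shape}")
    if not mask.any():
        raise DataError("granularity mask is empty")

    mu = img[mask].mean()
    if normalize_by_mean:
        if mu <= 0:
            raise DataError("cannot normalize by a non-positive masked mean")
        img = img / mu
        mu = 1.0
    filled = np.where(mask, img, mu)
    spectrum = np.fft.fft2(filled)
    energies = np.empty(bank.n_bands)
    for b, transfer in enumerate(bank.transfers):
        band_image = np.fft.ifft2(spectrum * transfer).real
        energies[b] = band_image[mask].var()
    return GranularitySpectrum(band_scales_px=bank.band_scales_px, energies=energies)


def pattern_table(
    records: Iterable[tuple[str, int, ReflectanceImage, np.ndarray]],
    bank: FilterBank,
    normalize_by_mean: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Four pattern statistics per specimen-week, as a tidy table.

    ``records`` yields ``(specimen_id, week, image, mask)``; the luminance
    plane (mean of visible channels) is analysed. Records whose size does
    not match the bank are reported in the returned error list and the run
    continues.
    """
    rows, errors = [], []
    for specimen_id, week, image, mask in records:
        try:
            spec = granularity_spectrum(image.luminance_plane(), mask, bank, normalize_by_mean)
        except (DataError, ConfigurationError) as exc:
            errors.append(f"{specimen_id}/week {week}: {exc}")
            continue
        rows.append(
            {
                "specimen_id": specimen_id,
                "week": int(week),
                "max_power": spec.max_power,
                "proportional_power": spec.proportional_power,
                "total_power": spec.total_power,
                "mean_power": spec.mean_power,
                "peak_scale_px": spec.peak_scale_px,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "week", "max_power", "proportional_power",
            "total_power", "mean_power", "peak_scale_px",
        ],
    )
    return table, errors
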