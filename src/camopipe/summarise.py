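"""Dimensionality reduction and treatment-trajectory summaries.

Colour (brightness, R, G, B, UV) and pattern (maximum, proportional, total,
mean power) variables are each collapsed to principal components before
trajectory analysis; group trajectories are summarised as per-cell mean,
standard error and n by treatment and week.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .types import PcaResult

__all__ = ["pca_reduce", "trajectory_summary"]


def pca_reduce(
    table: pd.DataFrame,
    standardize: bool = True,
    columns: Sequence[str] | None = None,
) -> PcaResult:
    """PCA of a records × variables table.

    Eigendecomposition of the correlation matrix when ``standardize`` is on
    (the default — channels live on different scales), of the covariance
    matrix otherwise. Records with missing cells are dropped with a warning.
    Component signs are oriented so each component's largest-magnitude
    loading is positive. The eigenvalue > 1 retention count is reported in
    the result, never applied silently.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    X = table[cols].to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ConfigurationError("PCA needs at least 2 variables")
    keep = ~np.isnan(X).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} records with missing cells", stacklevel=2)
        X = X[keep]
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 complete records")

    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = [c for c, s in zip(cols, sd) if s == 0]
        if constant:
            raise DataError(f"constant variable(s) under standardization: {constant}")
        Xc = Xc / sd
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # orient: largest-|loading| positive per component
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = Xc @ eigvecs
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PcaResult(
        variables=tuple(cols),
        loadings=eigvecs,
        scores=scores,
        eigenvalues=eigvals,
        variance_explained=frac,
        standardized=standardize,
        n_retained_kaiser=int((eigvals > 1.0).sum()),
    )


def trajectory_summary(
    table: pd.DataFrame,
    metrics: Sequence[str],
    group_cols: Sequence[str] = ("shade", "background", "week"),
) -> pd.DataFrame:
    """Per-cell mean, SE = sd/sqrt(n) and n for each metric by group.

    Empty cells are omitted; SE is NaN when n = 1. Rows are ordered by the
    grouping columns (week last, ascending), so the output is invariant to
    input record order.
    """
    for col in group_cols:
        if col not in table.columns:
            raise DataError(f"grouping column {col!r} missing from table")
    long = table.melt(
        id_vars=list(group_cols), value_vars=list(metrics),
        var_name="metric", value_name="value",
    ).dropna(subset=["value"])
    grouped = long.groupby([*group_cols, "metric"], sort=True)["value"]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, ["sd", "se"]] = np.nan
    return out.sort_values([*group_cols, "metric"], kind="mergesort").reset_index(drop=True)
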