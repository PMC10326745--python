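"""Abundance-matrix preprocessing: quantile normalization, missingness
filtering and K-nearest-neighbor imputation.

The canonical order is normalize -> filter (protein missing fraction
< 40% across all samples) -> impute, after which the matrix is complete
and ready for the statistical stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .data import AbundanceTable

__all__ = ["quantile_normalize", "filter_missing", "knn_impute", "preprocess"]


def quantile_normalize(table: AbundanceTable) -> AbundanceTable:
    """Force every sample onto the same abundance distribution.

    Each sample's observed values are replaced rank-wise by the mean of
    the per-sample sorted values at that rank (the reference
    distribution). Missing entries stay missing. Samples with unequal
    numbers of observed values are aligned on quantile position, with the
    reference interpolated linearly; rank ties receive the average of the
    tied ranks' reference values.
    """
    values = table.values.to_numpy(dtype=float, copy=True)
    n_prot = values.shape[0]
    obs_counts = (~np.isnan(values)).sum(axis=0)
    if (obs_counts < 2).any():
        bad = [s for s, c in zip(table.samples, obs_counts) if c < 2]
        raise ValueError(f"samples with fewer than 2 observed values: {bad}")

    # reference distribution on a common quantile grid
    grid = (np.arange(n_prot) + 0.5) / n_prot
    ref = np.zeros(n_prot)
    for j in range(values.shape[1]):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        pos = (np.arange(col.size) + 0.5) / col.size
        ref += np.interp(grid, pos, col)
    ref /= values.shape[1]

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        observed = ~np.isnan(values[:, j])
        col = values[observed, j]
        # average ranks handle ties; map rank to quantile position on [0, 1]
        ranks = pd.Series(col).rank(method="average").to_numpy()
        pos = (ranks - 0.5) / col.size
        out[observed, j] = np.interp(pos, grid, ref)
    frame = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return AbundanceTable(values=frame, design=table.design.copy())


def filter_missing(table: AbundanceTable, max_missing: float = 0.40) -> AbundanceTable:
    """Keep proteins whose missing fraction across all samples is < max_missing.

    Complete proteins always survive, including at max_missing = 0."""
    frac = table.values.isna().mean(axis=1)
    keep = (frac < max_missing) | (frac == 0)
    frame = table.values.loc[keep].copy()
    return AbundanceTable(values=frame, design=table.design.copy())


def knn_impute(table: AbundanceTable, k: int = 10) -> AbundanceTable:
    """Replace missing entries from the k nearest protein profiles.

    Neighbors are proteins (rows), ranked by Euclidean distance over
    co-observed samples; a missing entry becomes the mean of the
    neighbors' values in that sample. Proteins missing everywhere must be
    filtered beforehand. Observed entries are never altered.
    """
    values = table.values.to_numpy(dtype=float)
    if np.isnan(values).all(axis=1).any():
        raise ValueError("all-missing protein rows must be filtered before imputation")
    if not np.isnan(values).any():
        return AbundanceTable(values=table.values.copy(), design=table.design.copy())
    imputer = KNNImputer(n_neighbors=min(k, max(values.shape[0] - 1, 1)))
    filled = imputer.fit_transform(values)
    frame = pd.DataFrame(filled, index=table.values.index, columns=table.values.columns)
    return AbundanceTable(values=frame, design=table.design.copy())


def preprocess(table: AbundanceTable, max_missing: float = 0.40, k: int = 10) -> AbundanceTable:
    """normalize -> filter -> impute."""
    return knn_impute(filter_missing(quantile_normalize(table), max_missing), k)
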