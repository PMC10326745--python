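"""Consensus-clustering subtype discovery and cross-dataset signature
validation.

Consensus clustering repeats a base clusterer (agglomerative, average
linkage, 1 - Pearson correlation distance) on random sample subsets and
summarizes, for every sample pair, how often they land in the same
cluster when co-sampled. Stable structure shows as a near-binary
consensus matrix; the final labels come from hierarchical clustering of
1 - consensus. The number of clusters is scanned over 2..k_max, and the
area under the consensus CDF with its relative gain per added cluster
supports the choice of k (a manual override mirrors inspection-based
choices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import AbundanceTable
from . import de as _de

__all__ = ["ConsensusResult", "consensus_cluster", "subtype_markers", "validate_signature"]


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus_matrices: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    samples: list[str] = field(default_factory=list)

    def labels_for(self, k: int | None = None) -> pd.Series:
        return self.labels[self.chosen_k if k is None else k]


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples)."""
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _cut(dist: np.ndarray, k: int) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def _cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    if vals.size == 0:
        return 0.0
    # area under the empirical CDF on [0, 1]
    grid = np.linspace(0.0, 1.0, 101)
    cdf = np.searchsorted(vals, grid, side="right") / vals.size
    return float(np.trapezoid(cdf, grid))


def consensus_cluster(
    table: AbundanceTable,
    k_max: int = 6,
    reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    k_override: int | None = None,
    min_gain: float = 0.1,
    zscore: bool = True,
) -> ConsensusResult:
    """Subsampled consensus clustering of the samples of a complete matrix.

    For each k in 2..k_max, ``reps`` random subsets of
    ``subsample_frac`` of the samples are clustered; consensus(i, j) is
    the fraction of co-sampled runs in which i and j co-clustered. The
    default ``chosen_k`` is the largest k whose relative gain in
    consensus-CDF area is at least ``min_gain``; pass ``k_override`` to
    fix k by inspection.
    """
    if reps < 10:
        raise ValueError("reps must be at least 10")
    x = table.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present; run preprocessing first")
    samples = table.samples
    n = len(samples)
    if n < 2 * k_max:
        raise ValueError(f"need at least {2 * k_max} samples for k_max={k_max}")
    if zscore:
        sd = x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if np.ptp(x) == 0:
        raise ValueError("constant matrix cannot be clustered")

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))
    k_range = list(range(2, k_max + 1))
    consensus_matrices: dict[int, pd.DataFrame] = {}
    labels: dict[int, pd.Series] = {}
    cdf_areas: dict[int, float] = {}
    delta_areas: dict[int, float] = {}

    for k in k_range:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(reps):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            dist = _corr_distance(x[:, idx])
            assign = _cut(dist, k)
            ind = np.zeros((n,), dtype=bool)
            ind[idx] = True
            cosampled += np.outer(ind, ind)
            same = assign[:, None] == assign[None, :]
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        consensus_matrices[k] = pd.DataFrame(consensus, index=samples, columns=samples)
        final = _cut(np.clip(1.0 - consensus, 0.0, None), k)
        labels[k] = pd.Series(final, index=samples, name=f"k{k}")
        cdf_areas[k] = _cdf_area(consensus)

    prev = None
    for k in k_range:
        if prev is None:
            delta_areas[k] = cdf_areas[k]
        else:
            delta_areas[k] = (cdf_areas[k] - cdf_areas[prev]) / max(cdf_areas[prev], 1e-12)
        prev = k

    if k_override is not None:
        chosen_k = int(k_override)
    else:
        chosen_k = 2
        for k in k_range:
            if delta_areas[k] >= min_gain:
                chosen_k = k
            else:
                break
    return ConsensusResult(
        k_range=k_range,
        consensus_matrices=consensus_matrices,
        labels=labels,
        cdf_areas=cdf_areas,
        delta_areas=delta_areas,
        chosen_k=chosen_k,
        samples=samples,
    )


def subtype_markers(
    table: AbundanceTable, labels: pd.Series, fdr_cut: float = 0.001
) -> pd.DataFrame:
    """Moderated-t differential expression between two subtypes.

    ``labels`` assigns each sample of ``table`` to one of exactly two
    subtype labels. Markers are the proteins with fdr < fdr_cut; no
    fold-change cut is applied. Adds a boolean ``is_marker`` column.
    """
    labels = labels.astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two subtype labels, got {uniq}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each subtype needs at least 2 samples")
    sub = table.subset_samples(list(labels.index))
    sub = AbundanceTable(values=sub.values, design=labels.loc[sub.samples])
    results, _ = _de.fit_moderated_t(sub, case=uniq[0], control=uniq[1])
    results["is_marker"] = results["fdr"] < fdr_cut
    return results


def validate_signature(
    external: AbundanceTable,
    markers,
    k: int = 2,
    reps: int = 1000,
    seed: int | None = None,
    subsample_frac: float = 0.8,
) -> tuple[pd.Series, ConsensusResult]:
    """Consensus-cluster an external cohort on a marker signature.

    The external matrix is restricted to the shared marker identifiers
    (matching by gene symbol; at least 10 required), z-scored per gene
    and consensus-clustered at the fixed ``k``. Returns the labels and
    the full consensus result, for downstream survival comparison.
    """
    markers = list(markers)
    shared = [m for m in markers if m in set(external.proteins)]
    if len(shared) < 10:
        missing = sorted(set(markers) - set(external.proteins))
        raise ValueError(
            f"only {len(shared)} marker(s) shared with the external cohort; "
            f"missing e.g. {missing[:10]}"
        )
    sub = AbundanceTable(values=external.values.loc[shared].copy(), design=external.design.copy())
    result = consensus_cluster(
        sub, k_max=k, reps=reps, subsample_frac=subsample_frac, seed=seed, k_override=k
    )
    return result.labels_for(k), result
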