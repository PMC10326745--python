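"""Differential co-expression between two sample groups.

For every unordered protein pair the Pearson correlation is computed
separately in the case and control groups; the difference between the
two correlation coefficients is tested with Fisher's Z-transformation.
A differentially co-expressed link (DCL) must (1) be significantly
co-expressed (|r| > 0.5, FDR < 0.1) in at least one group, and (2) show
a correlation difference |r_case - r_ctrl| > 0.5 at FDR < 0.1.
Differentially co-expressed proteins (DCPs) carry more DCLs than a
global-rate binomial model expects.

The all-pairs stage is block-partitioned: standardized group matrices
are multiplied block-of-rows at a time, so only O(block * p) correlation
entries are ever materialized besides the flat per-pair result vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import AbundanceTable, CASE, CONTROL
from .stats import (
    bh_adjust,
    binomial_tail,
    correlation_pvalue,
    fisher_z_diff_vectorized,
)

__all__ = [
    "all_pair_correlations",
    "classify_dcl",
    "find_dcps",
    "link_pathway_enrichment",
    "LinkLookup",
]

log = logging.getLogger(__name__)

LINK_COLUMNS = [
    "protein_a", "protein_b",
    "r_case", "p_case", "fdr_case",
    "r_ctrl", "p_ctrl", "fdr_ctrl",
    "z_diff", "p_diff", "fdr_diff",
]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    return centered / norm


def all_pair_correlations(
    table: AbundanceTable,
    case: str = CASE,
    control: str = CONTROL,
    block_size: int = 1024,
) -> pd.DataFrame:
    """Per-group correlations and Fisher-Z difference test for every pair.

    Pairs are stored canonically (protein_a < protein_b
    lexicographically), so the output is invariant to the row order of
    the input matrix. Proteins with zero variance in either group are
    dropped entirely (their correlations are undefined) and excluded
    from all denominators. Per-group p-values and the difference p-value
    are each BH-adjusted across all tested pairs.
    """
    x1 = table.group_matrix(case)
    x2 = table.group_matrix(control)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher Z needs more than 3 samples per group")
    if table.n_missing:
        raise ValueError("missing values present; run preprocessing first")

    order = sorted(table.proteins)
    x1 = x1.loc[order].to_numpy(dtype=float)
    x2 = x2.loc[order].to_numpy(dtype=float)
    keep = (np.ptp(x1, axis=1) > 0) & (np.ptp(x2, axis=1) > 0)
    if not keep.all():
        log.warning("dropping %d zero-variance proteins from co-expression", int((~keep).sum()))
    proteins = [p for p, k in zip(order, keep) if k]
    z1 = _standardize_rows(x1[keep])
    z2 = _standardize_rows(x2[keep])
    p = len(proteins)
    if p < 2:
        raise ValueError("need at least 2 proteins with variance in both groups")

    ia_parts, ib_parts, rc_parts, rn_parts = [], [], [], []
    cols = np.arange(p)
    for i0 in range(0, p - 1, block_size):
        i1 = min(i0 + block_size, p)
        rows = np.arange(i0, i1)
        mask = cols[None, :] > rows[:, None]
        rc = z1[i0:i1] @ z1.T
        rn = z2[i0:i1] @ z2.T
        counts = p - rows - 1
        ia_parts.append(np.repeat(rows, counts).astype(np.int32))
        ib_parts.append(np.concatenate([np.arange(i + 1, p) for i in rows]).astype(np.int32))
        rc_parts.append(rc[mask])
        rn_parts.append(rn[mask])

    ia = np.concatenate(ia_parts)
    ib = np.concatenate(ib_parts)
    r_case = np.clip(np.concatenate(rc_parts), -1.0, 1.0)
    r_ctrl = np.clip(np.concatenate(rn_parts), -1.0, 1.0)

    p_case = correlation_pvalue(r_case, n1)
    p_ctrl = correlation_pvalue(r_ctrl, n2)
    z_diff, p_diff = fisher_z_diff_vectorized(r_case, n1, r_ctrl, n2)

    cat = pd.CategoricalDtype(categories=proteins)
    links = pd.DataFrame(
        {
            "protein_a": pd.Categorical.from_codes(ia, dtype=cat),
            "protein_b": pd.Categorical.from_codes(ib, dtype=cat),
            "r_case": r_case,
            "p_case": p_case,
            "fdr_case": bh_adjust(p_case),
            "r_ctrl": r_ctrl,
            "p_ctrl": p_ctrl,
            "fdr_ctrl": bh_adjust(p_ctrl),
            "z_diff": z_diff,
            "p_diff": p_diff,
            "fdr_diff": bh_adjust(p_diff),
        }
    )
    links.attrs["n_case"] = n1
    links.attrs["n_ctrl"] = n2
    return links


def classify_dcl(
    links: pd.DataFrame,
    rth: float = 0.5,
    qth: float = 0.1,
    r_diffth: float = 0.5,
    q_diffth: float = 0.1,
    diff_fdr_scope: str = "coexpressed",
) -> pd.DataFrame:
    """Flag differentially co-expressed links and classify their direction.

    is_dcl requires both criteria:
      (1) |r| > rth with FDR < qth in at least one group;
      (2) |r_case - r_ctrl| > r_diffth with difference-test FDR < q_diffth.

    ``diff_fdr_scope`` controls the family over which the difference-test
    FDR of criterion (2) is computed: "coexpressed" (default) adjusts
    within the pairs already passing criterion (1), matching the behavior
    of the reference differential co-expression tooling; "all" uses the
    adjustment over every tested pair carried in the input.

    dcl_class: "gain" if only the case correlation is significant, "loss"
    if only the control one, "reversal" if both are significant with
    opposite signs, "other" for the remaining DCLs.
    """
    out = links.copy()
    sig_case = (out["r_case"].abs() > rth) & (out["fdr_case"] < qth)
    sig_ctrl = (out["r_ctrl"].abs() > rth) & (out["fdr_ctrl"] < qth)
    cond1 = sig_case | sig_ctrl

    if diff_fdr_scope == "coexpressed":
        fdr_diff = out["fdr_diff"].to_numpy(copy=True)
        idx = np.flatnonzero(cond1.to_numpy())
        if idx.size:
            fdr_diff[idx] = bh_adjust(out["p_diff"].to_numpy()[idx])
        out["fdr_diff"] = fdr_diff
    elif diff_fdr_scope != "all":
        raise ValueError(f"unknown diff_fdr_scope: {diff_fdr_scope!r}")

    cond2 = ((out["r_case"] - out["r_ctrl"]).abs() > r_diffth) & (out["fdr_diff"] < q_diffth)
    out["is_dcl"] = (cond1 & cond2).to_numpy()

    dcl_class = np.full(len(out), None, dtype=object)
    is_dcl = out["is_dcl"].to_numpy()
    gain = is_dcl & sig_case.to_numpy() & ~sig_ctrl.to_numpy()
    loss = is_dcl & ~sig_case.to_numpy() & sig_ctrl.to_numpy()
    both = is_dcl & sig_case.to_numpy() & sig_ctrl.to_numpy()
    reversal = both & ((out["r_case"] * out["r_ctrl"]) < 0).to_numpy()
    dcl_class[gain] = "gain"
    dcl_class[loss] = "loss"
    dcl_class[reversal] = "reversal"
    dcl_class[both & ~reversal] = "other"
    out["dcl_class"] = dcl_class
    return out


def find_dcps(links: pd.DataFrame, qth: float = 0.1) -> pd.DataFrame:
    """Proteins with more DCLs than the global rate predicts.

    The null model is Binomial(n_links_tested, global DCL rate) per
    protein; the upper tail is BH-adjusted across proteins and DCP status
    requires fdr < qth.
    """
    if len(links) == 0:
        raise ValueError("no tested links")
    if "is_dcl" not in links:
        raise ValueError("links must be classified first (run classify_dcl)")
    proteins = list(links["protein_a"].cat.categories)
    n_prot = len(proteins)
    codes_a = links["protein_a"].cat.codes.to_numpy()
    codes_b = links["protein_b"].cat.codes.to_numpy()
    is_dcl = links["is_dcl"].to_numpy().astype(float)

    tested = np.bincount(codes_a, minlength=n_prot) + np.bincount(codes_b, minlength=n_prot)
    dcl = np.bincount(codes_a, weights=is_dcl, minlength=n_prot) + np.bincount(
        codes_b, weights=is_dcl, minlength=n_prot
    )
    rate = float(is_dcl.sum()) / len(links)
    k = dcl.astype(int)
    p = np.ones(n_prot)
    nonzero = k > 0
    p[nonzero] = sps.binom.sf(k[nonzero] - 1, tested[nonzero], rate)
    result = pd.DataFrame(
        {
            "n_links_tested": tested,
            "n_dcl": k,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=pd.Index(proteins, name="protein"),
    )
    result["is_dcp"] = result["fdr"] < qth
    result.attrs["dcl_rate"] = rate
    return result


def link_pathway_enrichment(
    links: pd.DataFrame, sets: dict[str, set[str]], min_pairs: int = 1
) -> pd.DataFrame:
    """Pathway enrichment of DCLs by Fisher's exact test.

    A link belongs to a gene set iff both proteins are members. Each set
    is tested on the 2x2 table {DCL vs non-DCL} x {in-set vs not} over
    all tested links, one-sided (greater); p-values are BH-adjusted
    across the tested sets. Sets whose members span fewer than
    ``min_pairs`` tested links are skipped.
    """
    if "is_dcl" not in links:
        raise ValueError("links must be classified first (run classify_dcl)")
    proteins = pd.Index(links["protein_a"].cat.categories)
    codes_a = links["protein_a"].cat.codes.to_numpy()
    codes_b = links["protein_b"].cat.codes.to_numpy()
    is_dcl = links["is_dcl"].to_numpy()
    total = len(links)
    total_dcl = int(is_dcl.sum())

    rows = []
    for name, members in sets.items():
        if not members:
            log.warning("skipping empty gene set %r", name)
            continue
        member_mask = np.asarray(proteins.isin(members))
        in_set = member_mask[codes_a] & member_mask[codes_b]
        n_in = int(in_set.sum())
        if n_in < min_pairs:
            log.warning("skipping gene set %r with no tested pairs", name)
            continue
        a = int((in_set & is_dcl).sum())
        p = float(sps.hypergeom.sf(a - 1, total, total_dcl, n_in)) if a else 1.0
        dcl_idx = np.flatnonzero(in_set & is_dcl)
        pairs = ";".join(
            f"{links['protein_a'].iat[i]}-{links['protein_b'].iat[i]}" for i in dcl_idx[:50]
        )
        rows.append(
            {
                "set_name": name,
                "n_pairs_in_set": n_in,
                "n_dcl_in_set": a,
                "p": p,
                "dcl_pairs": pairs,
            }
        )
    result = pd.DataFrame(rows, columns=["set_name", "n_pairs_in_set", "n_dcl_in_set", "p", "dcl_pairs"])
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
    else:
        result["fdr"] = []
    return result.sort_values("p", kind="stable").reset_index(drop=True)


class LinkLookup:
    """O(log n) membership and row lookup for canonical protein pairs."""

    def __init__(self, links: pd.DataFrame):
        self.proteins = pd.Index(links["protein_a"].cat.categories)
        k = len(self.proteins)
        a = links["protein_a"].cat.codes.to_numpy().astype(np.int64)
        b = links["protein_b"].cat.codes.to_numpy().astype(np.int64)
        keys = a * k + b
        self._order = np.argsort(keys, kind="stable")
        self._sorted_keys = keys[self._order]
        self._is_dcl = (
            links["is_dcl"].to_numpy()[self._order]
            if "is_dcl" in links
            else np.zeros(len(links), dtype=bool)
        )
        self.n_tested = len(links)
        self.n_dcl = int(self._is_dcl.sum())
        self._code = {p: i for i, p in enumerate(self.proteins)}

    def row_indices(self, pairs) -> np.ndarray:
        """Original row index in the link table per pair; -1 if untested."""
        k = len(self.proteins)
        keys = []
        for a, b in pairs:
            ca, cb = self._code.get(a, -1), self._code.get(b, -1)
            if ca < 0 or cb < 0:
                keys.append(-1)
            else:
                lo, hi = min(ca, cb), max(ca, cb)
                keys.append(lo * k + hi)
        keys = np.asarray(keys, dtype=np.int64)
        pos = np.searchsorted(self._sorted_keys, keys)
        pos = np.clip(pos, 0, len(self._sorted_keys) - 1)
        found = (keys >= 0) & (self._sorted_keys[pos] == keys)
        out = np.where(found, self._order[pos], -1)
        return out

    def tested(self, pairs) -> np.ndarray:
        return self.row_indices(pairs) >= 0

    def is_dcl(self, pairs) -> np.ndarray:
        rows = self.row_indices(pairs)
        k = len(self.proteins)
        out = np.zeros(len(rows), dtype=bool)
        ok = rows >= 0
        if ok.any():
            # map original rows back into sorted order for the flag array
            inv = np.empty(self.n_tested, dtype=np.int64)
            inv[self._order] = np.arange(self.n_tested)
            out[ok] = self._is_dcl[inv[rows[ok]]]
        return out
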