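"""Over-representation analysis of protein lists against gene-set
collections (GMT), plus comparison of two enrichment runs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = ["ora", "compare_enrichments"]

log = logging.getLogger(__name__)


def ora(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    min_overlap: int = 1,
    fdr_cut: float = 0.1,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    The universe is the background of quantifiable proteins; sets are
    intersected with it and the query must be a subset of it. Returns a
    DataFrame sorted by p with columns set_name, overlap, set_size,
    query_size, universe_size, p, fdr, significant.
    """
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        if not members:
            log.warning("skipping gene set %r with no member in the universe", name)
            continue
        overlap = len(members & query)
        if overlap < min_overlap:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(overlap - 1, n_univ, len(members), n_query))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": n_univ,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    result["fdr"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    result["significant"] = result["fdr"] < fdr_cut if len(result) else []
    return result.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def compare_enrichments(
    a: pd.DataFrame, b: pd.DataFrame, alpha: float = 0.1
) -> dict[str, set[str]]:
    """Partition significant set names of two runs on the same collection
    into shared / a_only / b_only."""
    if set(a["set_name"]) != set(b["set_name"]):
        raise ValueError("enrichment results come from different collections")
    sig_a = set(a.loc[a["fdr"] < alpha, "set_name"])
    sig_b = set(b.loc[b["fdr"] < alpha, "set_name"])
    return {
        "shared": sig_a & sig_b,
        "a_only": sig_a - sig_b,
        "b_only": sig_b - sig_a,
    }
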