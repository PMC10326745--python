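"""Network integration of differential expression and co-expression.

Each protein's *star* (the protein plus its direct interaction
neighbors) is scored for local enrichment of small differential
expression p-values with an order-statistic score calibrated by
resampling; significant stars are then filtered for enrichment of
differentially co-expressed links, their non-DCL edges pruned, and the
maximum connected components merged into a single unified dysregulated
network.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .dce import LinkLookup
from .stats import bh_adjust, holm_adjust

__all__ = [
    "load_ppi",
    "lean_scan",
    "filter_stars_by_dc",
    "build_unified_network",
    "annotate_nodes",
    "extract_geneset_subnetwork",
]

log = logging.getLogger(__name__)


def load_ppi(path, score_min: float | None = None) -> nx.Graph:
    """Read an undirected PPI edge list.

    Accepts either a plain two-column file (geneA <tab> geneB) or the
    HIPPIE-style six-column dialect (geneA, idA, geneB, idB, confidence,
    evidence). Self-interactions are removed, duplicate edges collapse,
    and ``score_min`` (if given) drops low-confidence HIPPIE edges.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 5:
                a, b = fields[0], fields[2]
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed confidence on line {lineno}") from exc
                if score_min is not None and score < score_min:
                    continue
            elif len(fields) == 2:
                a, b = fields
                score = None
            else:
                raise ValueError(f"{path}: malformed line {lineno} ({len(fields)} fields)")
            if not a or not b:
                raise ValueError(f"{path}: empty identifier on line {lineno}")
            if a == b:
                continue  # self-interactions are removed
            if score is None:
                graph.add_edge(a, b)
            else:
                graph.add_edge(a, b, confidence=score)
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no usable edges")
    return graph


def _lean_raw_scores(sorted_p: np.ndarray) -> np.ndarray:
    """Order-statistic star score, rows = stars of equal size m.

    For sorted member p-values p(1) <= ... <= p(m) the score is
    min_k P(Binomial(m, p(k)) >= k): the most surprising prefix of the
    star under independent uniform p-values.
    """
    n, m = sorted_p.shape
    k = np.arange(1, m + 1)
    tails = sps.binom.sf(k[None, :] - 1, m, sorted_p)
    return tails.min(axis=1)


def lean_scan(
    network: nx.Graph,
    de_p: pd.Series | dict,
    n_perm: int = 10_000,
    seed: int | None = None,
    fdr_cut: float = 0.1,
) -> pd.DataFrame:
    """Local enrichment scan of every star in the network.

    ``de_p`` maps protein -> differential-expression p-value; stars are
    restricted to scored nodes and unscored centers are skipped (a
    protein never quantified carries no evidence). The raw
    order-statistic score is calibrated to an empirical p-value against
    ``n_perm`` random same-size member draws (with replacement) from the
    global p-value pool, then BH-adjusted across centers.

    Returns a DataFrame indexed by center with columns members (tuple),
    size, lean_score, lean_p, lean_fdr, significant.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse calibration", stacklevel=2)
    de_p = pd.Series(de_p, dtype=float)
    scored = set(de_p.index) & set(network.nodes)
    pool = de_p.loc[sorted(scored)].to_numpy()
    if pool.size == 0:
        raise ValueError("no network node carries a differential-expression p-value")
    rng = np.random.default_rng(seed)

    centers, members_list, sizes, obs_scores = [], [], [], []
    for center in sorted(scored):
        members = [center] + [v for v in network.neighbors(center) if v in scored]
        m = len(members)
        centers.append(center)
        members_list.append(tuple(sorted(members)))
        sizes.append(m)
        obs = _lean_raw_scores(np.sort(de_p.loc[members].to_numpy())[None, :])[0]
        obs_scores.append(obs)
    sizes = np.asarray(sizes)
    obs_scores = np.asarray(obs_scores)

    # one shared null per distinct star size: random size-m member sets
    lean_p = np.empty(len(centers))
    for m in np.unique(sizes):
        null = _lean_raw_scores(np.sort(rng.choice(pool, size=(n_perm, m)), axis=1))
        null.sort()
        which = sizes == m
        counts = np.searchsorted(null, obs_scores[which], side="right")
        lean_p[which] = (counts + 1.0) / (n_perm + 1.0)

    result = pd.DataFrame(
        {
            "members": members_list,
            "size": sizes,
            "lean_score": obs_scores,
            "lean_p": lean_p,
            "lean_fdr": bh_adjust(lean_p),
        },
        index=pd.Index(centers, name="center"),
    )
    result["significant"] = result["lean_fdr"] < fdr_cut
    return result


def filter_stars_by_dc(
    stars: pd.DataFrame,
    links: pd.DataFrame | LinkLookup,
    network: nx.Graph,
    alpha: float = 0.1,
    background: str = "tested",
) -> pd.DataFrame:
    """Keep significant stars enriched for differentially co-expressed links.

    For each star passing the local-enrichment FDR cut, a one-sided
    Fisher's exact test compares {DCL vs non-DCL} among the star's tested
    edges against the background, which is either all tested pairs
    outside the star (background="tested", default) or the network's
    tested edges outside the star (background="ppi"). The p-values are
    Holm-adjusted across the significant stars and stars with adjusted
    p < alpha are retained.
    """
    lookup = links if isinstance(links, LinkLookup) else LinkLookup(links)
    if background not in ("tested", "ppi"):
        raise ValueError(f"unknown background: {background!r}")
    candidates = stars[stars["significant"]].copy()

    if background == "ppi":
        ppi_pairs = list(network.edges)
        ppi_tested = lookup.tested(ppi_pairs)
        ppi_dcl = lookup.is_dcl(ppi_pairs)
        bg_total, bg_dcl = int(ppi_tested.sum()), int(ppi_dcl.sum())
    else:
        bg_total, bg_dcl = lookup.n_tested, lookup.n_dcl

    keep_rows, p_vals, edge_counts, dcl_counts = [], [], [], []
    for center, row in candidates.iterrows():
        members = set(row["members"])
        star_edges = [e for e in network.subgraph(members).edges]
        tested = lookup.tested(star_edges)
        n_tested = int(tested.sum())
        if n_tested == 0:
            log.warning("star %s has no tested edges; excluded", center)
            continue
        n_dcl = int(lookup.is_dcl(star_edges).sum())
        a, b = n_dcl, n_tested - n_dcl
        c, d = bg_dcl - a, (bg_total - n_tested) - (bg_dcl - a)
        p = float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)) if a else 1.0
        keep_rows.append(center)
        p_vals.append(p)
        edge_counts.append(n_tested)
        dcl_counts.append(n_dcl)

    out = candidates.loc[keep_rows].copy()
    out["n_edges_tested"] = edge_counts
    out["n_edges_dcl"] = dcl_counts
    out["dc_fisher_p"] = p_vals
    out["dc_holm_p"] = holm_adjust(np.asarray(p_vals)) if p_vals else []
    out["retained"] = out["dc_holm_p"] < alpha
    return out


def _max_component(graph: nx.Graph) -> set:
    """Component with the most nodes; ties by edge count, then by the
    lexicographically smallest sorted node tuple."""
    comps = list(nx.connected_components(graph))
    if not comps:
        return set()
    return min(
        comps,
        key=lambda c: (
            -len(c),
            -graph.subgraph(c).number_of_edges(),
            tuple(sorted(c)),
        ),
    )


def build_unified_network(
    stars: pd.DataFrame,
    network: nx.Graph,
    links: pd.DataFrame,
) -> nx.Graph:
    """Merge DC-pruned stars into the unified dysregulated network.

    Within each retained star the induced edges that are not DCLs are
    dropped; the maximum connected component of the remainder is kept;
    all components are unioned (idempotent on shared nodes/edges). Every
    unified edge is by construction both a network edge and a DCL, and it
    carries the link statistics.
    """
    lookup = LinkLookup(links)
    kept = stars[stars["retained"]] if "retained" in stars else stars
    unified = nx.Graph()
    for _, row in kept.iterrows():
        members = set(row["members"])
        star_edges = list(network.subgraph(members).edges)
        if not star_edges:
            continue
        flags = lookup.is_dcl(star_edges)
        pruned = nx.Graph([e for e, f in zip(star_edges, flags) if f])
        if pruned.number_of_nodes() == 0:
            continue
        component = _max_component(pruned)
        unified.update(pruned.subgraph(component))

    if unified.number_of_edges():
        edges = list(unified.edges)
        rows = lookup.row_indices(edges)
        stat_cols = [c for c in ("r_case", "r_ctrl", "z_diff", "fdr_diff", "dcl_class") if c in links]
        for (u, v), r in zip(edges, rows):
            rec = links.iloc[int(r)]
            attrs = {c: rec[c] for c in stat_cols}
            unified.edges[u, v].update(
                {k: (float(v_) if isinstance(v_, (int, float, np.floating)) else str(v_)) for k, v_ in attrs.items()}
            )
    for i, comp in enumerate(sorted(nx.connected_components(unified), key=lambda c: (-len(c), sorted(c)))):
        for node in comp:
            unified.nodes[node]["component"] = i
    return unified


def annotate_nodes(
    net: nx.Graph,
    disease_genes: set[str] | None = None,
    druggable: set[str] | None = None,
    de_results: pd.DataFrame | None = None,
    dcps: pd.DataFrame | None = None,
) -> dict[str, int]:
    """Flag unified-network nodes by exact identifier match.

    Sets node attributes disease_gene, druggable, de_status and is_dcp in
    place and returns the overlap counts.
    """
    counts = {}
    for name, id_set in (("disease_gene", disease_genes), ("druggable", druggable)):
        if id_set is None:
            continue
        hits = 0
        for node in net.nodes:
            flag = node in id_set
            net.nodes[node][name] = bool(flag)
            hits += flag
        counts[name] = hits
    if de_results is not None:
        for node in net.nodes:
            status = de_results["status"].get(node, "ns") if "status" in de_results else "ns"
            net.nodes[node]["de_status"] = str(status)
        counts["de"] = sum(1 for n in net.nodes if net.nodes[n]["de_status"] != "ns")
    if dcps is not None:
        flagged = set(dcps.index[dcps["is_dcp"]]) if "is_dcp" in dcps else set()
        for node in net.nodes:
            net.nodes[node]["is_dcp"] = node in flagged
        counts["dcp"] = sum(1 for n in net.nodes if net.nodes[n]["is_dcp"])
    return counts


def extract_geneset_subnetwork(
    net: nx.Graph, genes: set[str], max_linkers: int = 2
) -> nx.Graph:
    """Gene-set neighborhood of the unified network.

    Induces the subgraph on the gene set and reconnects its components
    through shortest paths of at most ``max_linkers`` intermediate nodes;
    linker nodes are flagged with the node attribute ``linker=True``.
    """
    if not genes:
        raise ValueError("empty gene set")
    present = sorted(genes & set(net.nodes))
    if not present:
        log.warning("no gene-set member found in the network")
        return nx.Graph()
    sub = net.subgraph(present).copy()
    keep_nodes = set(present)
    for i, u in enumerate(present):
        for v in present[i + 1 :]:
            if nx.has_path(net, u, v):
                path = nx.shortest_path(net, u, v)
                if 0 < len(path) - 2 <= max_linkers:
                    keep_nodes.update(path)
                elif len(path) - 2 == 0:
                    keep_nodes.update(path)
    out = net.subgraph(keep_nodes).copy()
    for node in out.nodes:
        out.nodes[node]["linker"] = node not in genes
    return out
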