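"""PPI loading, local enrichment scan, star filtering and the unified
network construction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coexnet.network import (
    _lean_raw_scores,
    annotate_nodes,
    build_unified_network,
    extract_geneset_subnetwork,
    filter_stars_by_dc,
    lean_scan,
    load_ppi,
)
from coexnet.stats import fisher_exact_enrichment
from test_dce import make_links


# ---------------------------------------------------------------------------
# load_ppi


def test_load_ppi_hippie_dialect(tmp_path):
    f = tmp_path / "ppi.tsv"
    f.write_text(
        "A\tA_id\tB\tB_id\t0.9\texp\n"
        "B\tB_id\tA\tA_id\t0.9\texp\n"  # duplicate, reversed
        "A\tA_id\tA\tA_id\t0.9\texp\n"  # self-loop
        "C\tC_id\tD\tD_id\t0.3\texp\n"
        "D\tD_id\tE\tE_id\t0.8\texp\n"
    )
    g = load_ppi(f)
    assert set(g.nodes) == {"A", "B", "C", "D", "E"}
    assert g.number_of_edges() == 3
    g_filtered = load_ppi(f, score_min=0.5)
    assert not g_filtered.has_edge("C", "D")


def test_load_ppi_two_column_and_errors(tmp_path):
    f = tmp_path / "edges.tsv"
    f.write_text("A\tB\nB\tC\n")
    g = load_ppi(f)
    assert g.number_of_edges() == 2

    bad = tmp_path / "bad.tsv"
    bad.write_text("A\tB\nA\tB\tC\n")
    with pytest.raises(ValueError, match="line 2"):
        load_ppi(bad)

    empty = tmp_path / "empty.tsv"
    empty.write_text("A\tA_id\tA\tA_id\t0.9\texp\n")
    with pytest.raises(ValueError, match="no usable edges"):
        load_ppi(empty)


# ---------------------------------------------------------------------------
# lean_scan


def test_lean_raw_score_is_min_binomial_tail():
    # star p-values (0.001, 0.5, 0.9): best prefix is k=1 -> 1 - 0.999^3
    score = _lean_raw_scores(np.array([[0.001, 0.5, 0.9]]))[0]
    assert score == pytest.approx(1 - 0.999**3, rel=1e-9)
    assert score == pytest.approx(0.002997, abs=1e-6)


def test_lean_single_node_star_scores_its_own_p():
    g = nx.Graph()
    g.add_node("A")
    de_p = pd.Series({"A": 0.2})
    stars = lean_scan(g, de_p, n_perm=200, seed=1)
    assert stars.loc["A", "lean_score"] == pytest.approx(0.2)


def test_lean_all_null_pvalues_give_no_hits():
    g = nx.barabasi_albert_graph(60, 2, seed=1)
    de_p = pd.Series(1.0 - 1e-9, index=list(g.nodes))
    stars = lean_scan(g, de_p, n_perm=300, seed=2)
    assert not stars["significant"].any()


def test_lean_unscored_nodes_are_excluded():
    g = nx.path_graph(4)
    de_p = pd.Series({0: 0.5, 1: 0.5})  # nodes 2, 3 unscored
    stars = lean_scan(g, de_p, n_perm=200, seed=0)
    assert set(stars.index) == {0, 1}
    assert stars.loc[1, "members"] == (0, 1)


def test_lean_null_pvalues_are_uniform():
    """Calibrated p-values under the global null pass a KS uniformity check
    (500 centers, 2000 permutations, fixed seed; the KS statistic of even
    perfectly uniform draws exceeds 0.05 for ~1 seed in 6 at n=500)."""
    g = nx.barabasi_albert_graph(500, 2, seed=11)
    de_p = pd.Series(np.random.default_rng(1).uniform(size=500), index=list(g.nodes))
    stars = lean_scan(g, de_p, n_perm=2000, seed=3)
    ks = sps.kstest(stars["lean_p"], "uniform").statistic
    assert ks < 0.05


def test_lean_warns_on_tiny_permutation_count():
    g = nx.path_graph(3)
    with pytest.warns(UserWarning):
        lean_scan(g, pd.Series(0.5, index=list(g.nodes)), n_perm=50, seed=0)


# ---------------------------------------------------------------------------
# filter_stars_by_dc


def _star_frame(center, members, significant=True):
    return pd.DataFrame(
        {
            "members": [tuple(sorted(members))],
            "size": [len(members)],
            "lean_score": [0.001],
            "lean_p": [0.001],
            "lean_fdr": [0.01],
            "significant": [significant],
        },
        index=pd.Index([center], name="center"),
    )


def test_star_enrichment_matches_fisher_oracle():
    """A star with 8/10 DCL edges against a 100/1000 background survives
    filtering, with the p-value of the one-sided Fisher test."""
    hub = "HUB"
    spokes = [f"s{i:02d}" for i in range(10)]
    star_pairs = [(hub, s) for s in spokes]
    star_flags = [True] * 8 + [False] * 2
    bg_pairs = [(f"x{i:03d}", f"y{i:03d}") for i in range(990)]
    bg_flags = [True] * 92 + [False] * 898
    links = make_links(star_pairs + bg_pairs, star_flags + bg_flags)
    g = nx.star_graph([hub] + spokes)
    stars = _star_frame(hub, [hub] + spokes)
    out = filter_stars_by_dc(stars, links, g, alpha=0.1)
    expected = fisher_exact_enrichment(8, 2, 92, 898, alternative="greater")
    assert out.loc[hub, "dc_fisher_p"] == pytest.approx(expected, rel=1e-9)
    assert bool(out.loc[hub, "retained"])


def test_star_without_dcl_edges_is_dropped():
    hub = "H"
    spokes = ["a", "b", "c"]
    links = make_links(
        [(hub, s) for s in spokes] + [("u", "v"), ("w", "z")],
        [False, False, False, True, True],
    )
    g = nx.star_graph([hub] + spokes)
    out = filter_stars_by_dc(_star_frame(hub, [hub] + spokes), links, g)
    assert out.loc[hub, "dc_fisher_p"] == pytest.approx(1.0)
    assert not bool(out.loc[hub, "retained"])


def test_saturated_dcl_background_enriches_nothing():
    hub = "H"
    spokes = ["a", "b"]
    links = make_links([(hub, s) for s in spokes] + [("u", "v")], [True, True, True])
    g = nx.star_graph([hub] + spokes)
    out = filter_stars_by_dc(_star_frame(hub, [hub] + spokes), links, g)
    assert out.loc[hub, "dc_fisher_p"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# build_unified_network


def _retained(star_frame):
    star_frame = star_frame.copy()
    star_frame["retained"] = True
    return star_frame


def test_pruning_keeps_max_component_only():
    g = nx.Graph([("a", "b"), ("a", "c")])
    links = make_links([("a", "b"), ("a", "c")], [True, False])
    uni = build_unified_network(_retained(_star_frame("a", ["a", "b", "c"])), g, links)
    assert set(uni.nodes) == {"a", "b"}
    assert set(map(frozenset, uni.edges)) == {frozenset({"a", "b"})}


def test_no_dcl_edges_give_empty_network():
    g = nx.Graph([("a", "b")])
    links = make_links([("a", "b")], [False])
    uni = build_unified_network(_retained(_star_frame("a", ["a", "b"])), g, links)
    assert uni.number_of_nodes() == 0


def test_shared_edges_union_idempotently():
    g = nx.Graph([("a", "b"), ("b", "c")])
    links = make_links([("a", "b"), ("b", "c")], [True, True])
    stars = pd.concat(
        [_star_frame("a", ["a", "b"]), _star_frame("b", ["a", "b", "c"])]
    )
    uni = build_unified_network(_retained(stars), g, links)
    assert uni.number_of_edges() == 2
    assert set(uni.nodes) == {"a", "b", "c"}


def test_union_is_order_independent(small_dataset, rng):
    from coexnet.de import fit_moderated_t
    from coexnet.dce import all_pair_correlations, classify_dcl
    from coexnet.preprocess import preprocess

    _, table, network, truth, _ = small_dataset
    proc = preprocess(table)
    res, _ = fit_moderated_t(proc)
    links = classify_dcl(all_pair_correlations(proc))
    stars = lean_scan(network, res["p"], n_perm=500, seed=4)
    filt = filter_stars_by_dc(stars, links, network)
    kept = filt[filt["retained"]]
    uni1 = build_unified_network(kept, network, links)
    shuffled = kept.sample(frac=1.0, random_state=9)
    uni2 = build_unified_network(shuffled, network, links)
    assert set(uni1.nodes) == set(uni2.nodes)
    assert set(map(frozenset, uni1.edges)) == set(map(frozenset, uni2.edges))
    # every unified edge is both a PPI edge and a DCL
    dcl = links[links["is_dcl"]]
    dcl_pairs = {frozenset((a, b)) for a, b in zip(dcl["protein_a"].astype(str), dcl["protein_b"].astype(str))}
    ppi_pairs = {frozenset(e) for e in network.edges}
    assert {frozenset(e) for e in uni1.edges} <= (dcl_pairs & ppi_pairs)


# ---------------------------------------------------------------------------
# annotate_nodes / extract_geneset_subnetwork


def test_annotate_counts_exact_matches():
    g = nx.path_graph(["a", "b", "c", "d"])
    counts = annotate_nodes(g, disease_genes={"a", "z"}, druggable=set())
    assert counts == {"disease_gene": 1, "druggable": 0}
    assert g.nodes["a"]["disease_gene"] and not g.nodes["b"]["disease_gene"]
    counts_all = annotate_nodes(g, disease_genes={"a", "b", "c", "d"})
    assert counts_all["disease_gene"] == 4


def test_extract_single_member_and_linker_path():
    g = nx.path_graph(["a", "m", "b"])
    single = extract_geneset_subnetwork(g, {"a"})
    assert set(single.nodes) == {"a"}
    path = extract_geneset_subnetwork(g, {"a", "b"}, max_linkers=1)
    assert set(path.nodes) == {"a", "m", "b"}
    assert path.nodes["m"]["linker"] and not path.nodes["a"]["linker"]
    too_far = extract_geneset_subnetwork(nx.path_graph(["a", "x", "y", "b"]), {"a", "b"}, max_linkers=1)
    assert set(too_far.nodes) == {"a", "b"}


def test_extract_handles_absent_geneset():
    g = nx.path_graph(["a", "b"])
    out = extract_geneset_subnetwork(g, {"q", "r"})
    assert out.number_of_nodes() == 0
    with pytest.raises(ValueError):
        extract_geneset_subnetwork(g, set())
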