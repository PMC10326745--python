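"""Stage orchestration: run any single stage or the whole pipeline.

Every stage reads plain-text inputs, writes plain-text outputs into the
configured output directory, and contributes record counts to a JSON run
manifest, so a full run leaves an auditable funnel: proteins retained ->
DE calls -> DCLs/DCPs -> significant and retained stars -> unified
network -> subtypes and markers -> survival comparison.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import de as de_mod
from . import dce as dce_mod
from . import enrichment as enrich_mod
from . import network as net_mod
from . import preprocess as prep_mod
from . import subtype as sub_mod
from . import survival as surv_mod
from .config import PipelineConfig
from .data import (
    AbundanceTable,
    read_abundance,
    read_gene_sets,
    read_id_list,
    read_survival,
    write_abundance,
    write_edge_list,
    write_gmt,
    write_hippie_edge_list,
    write_survival,
)
from .simulate import SyntheticConfig, generate_dataset, generate_mrna_mirror, make_gene_sets

log = logging.getLogger(__name__)

STAGES = ["preprocess", "de", "dce", "network", "enrich", "subtype", "survival"]


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no {what} file configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def _out(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def simulate(sim_config: SyntheticConfig, outdir) -> dict:
    """Write a complete synthetic input bundle + truth JSON to outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table, network, truth, survival = generate_dataset(sim_config)
    write_abundance(table, out / "abundance.tsv", out / "design.tsv")
    write_hippie_edge_list(sorted(network.edges), out / "ppi.tsv")
    sets = make_gene_sets(truth, table.proteins, seed=sim_config.seed)
    write_gmt(sets, out / "genesets.gmt")
    write_survival(survival, out / "survival.tsv")
    truth.to_json(out / "truth.json")
    mirror, mirror_surv = generate_mrna_mirror(truth, sim_config)
    write_abundance(mirror, out / "mirror_abundance.tsv", out / "mirror_design.tsv")
    write_survival(mirror_surv, out / "mirror_survival.tsv")
    return {
        "n_proteins": sim_config.n_proteins,
        "n_samples": sim_config.n_case + sim_config.n_ctrl,
        "ppi_edges": network.number_of_edges(),
    }


def stage_preprocess(config: PipelineConfig) -> AbundanceTable:
    table = read_abundance(
        _require(config.abundance, "abundance"), _require(config.design, "design")
    )
    out = _out(config)
    processed = prep_mod.preprocess(table, max_missing=config.max_missing, k=config.knn_k)
    write_abundance(processed, out / "processed.tsv", out / "processed_design.tsv")
    log.info("preprocess: %d -> %d proteins", len(table.proteins), len(processed.proteins))
    return processed


def _load_processed(config: PipelineConfig) -> AbundanceTable:
    out = _out(config)
    return read_abundance(
        _require(out / "processed.tsv", "processed matrix"),
        _require(out / "processed_design.tsv", "processed design"),
    )


def stage_de(config: PipelineConfig, table: AbundanceTable | None = None) -> pd.DataFrame:
    table = table if table is not None else _load_processed(config)
    results, prior = de_mod.fit_moderated_t(table)
    results = de_mod.call_de(results, fdr_cut=config.de_fdr, fc_cut=config.fc_cut)
    results.attrs["d0"] = prior.d0
    results.attrs["s0_sq"] = prior.s0_sq
    out = _out(config)
    results.round(10).to_csv(out / "de_results.tsv", sep="\t", index_label="protein")
    return results


def stage_dce(config: PipelineConfig, table: AbundanceTable | None = None) -> pd.DataFrame:
    table = table if table is not None else _load_processed(config)
    links = dce_mod.all_pair_correlations(table)
    links = dce_mod.classify_dcl(
        links,
        rth=config.rth,
        qth=config.qth,
        r_diffth=config.r_diffth,
        q_diffth=config.q_diffth,
        diff_fdr_scope=config.diff_fdr_scope,
    )
    out = _out(config)
    dcls = links[links["is_dcl"]]
    dcls.round(10).to_csv(out / "dcl.tsv", sep="\t", index=False)
    dcps = dce_mod.find_dcps(links, qth=config.dcp_fdr)
    dcps.round(10).to_csv(out / "dcp.tsv", sep="\t")
    return links


def stage_network(
    config: PipelineConfig,
    de_results: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    if de_results is None:
        path = _require(Path(config.outdir) / "de_results.tsv", "DE results")
        de_results = pd.read_csv(path, sep="\t", index_col="protein")
    if links is None:
        links = stage_dce(config)  # full link statistics are recomputed, not stored
    ppi = net_mod.load_ppi(_require(config.ppi, "PPI"))
    stars = net_mod.lean_scan(
        ppi, de_results["p"], n_perm=config.lean_perm, seed=config.seed, fdr_cut=config.lean_fdr
    )
    filtered = net_mod.filter_stars_by_dc(
        stars, links, ppi, alpha=config.star_alpha, background=config.star_background
    )
    unified = net_mod.build_unified_network(filtered, ppi, links)
    dcps = dce_mod.find_dcps(links, qth=config.dcp_fdr)
    annotations = {}
    disease = read_id_list(config.disease_genes) if config.disease_genes else None
    drugs = read_id_list(config.druggable) if config.druggable else None
    annotations = net_mod.annotate_nodes(
        unified, disease_genes=disease, druggable=drugs, de_results=de_results, dcps=dcps
    )
    out = _out(config)
    stars.drop(columns=["members"]).round(10).to_csv(out / "stars.tsv", sep="\t")
    filtered.drop(columns=["members"]).round(10).to_csv(out / "stars_filtered.tsv", sep="\t")
    edge_rows = [
        {"protein_a": u, "protein_b": v, **data} for u, v, data in sorted(unified.edges(data=True))
    ]
    pd.DataFrame(edge_rows).to_csv(out / "unified_edges.tsv", sep="\t", index=False)
    nx.write_graphml(unified, out / "unified_network.graphml")
    (out / "annotation_counts.json").write_text(json.dumps(annotations, sort_keys=True))
    stars_all = stars.copy()
    stars_all.attrs["filtered"] = filtered
    return unified, stars_all


def stage_enrich(
    config: PipelineConfig,
    de_results: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
    unified: nx.Graph | None = None,
) -> dict[str, pd.DataFrame]:
    sets = read_gene_sets(_require(config.gmt, "gene sets (GMT)"))
    if de_results is None:
        path = _require(Path(config.outdir) / "de_results.tsv", "DE results")
        de_results = pd.read_csv(path, sep="\t", index_col="protein")
    universe = set(de_results.index)
    out = _out(config)
    results: dict[str, pd.DataFrame] = {}

    de_set = set(de_results.index[de_results["status"] != "ns"])
    if de_set:
        results["de"] = enrich_mod.ora(de_set, sets, universe, fdr_cut=config.enrich_fdr)
        results["de"].round(10).to_csv(out / "enrichment_de.tsv", sep="\t", index=False)
    if links is not None:
        results["links"] = dce_mod.link_pathway_enrichment(links, sets)
        results["links"].round(10).to_csv(out / "enrichment_links.tsv", sep="\t", index=False)
        dcps = dce_mod.find_dcps(links, qth=config.dcp_fdr)
        dcp_set = set(dcps.index[dcps["is_dcp"]])
        if dcp_set:
            results["dcp"] = enrich_mod.ora(dcp_set, sets, universe, fdr_cut=config.enrich_fdr)
            results["dcp"].round(10).to_csv(out / "enrichment_dcp.tsv", sep="\t", index=False)
    if unified is not None and unified.number_of_nodes():
        query = set(unified.nodes) & universe
        if query:
            results["unified"] = enrich_mod.ora(query, sets, universe, fdr_cut=config.enrich_fdr)
            results["unified"].round(10).to_csv(out / "enrichment_unified.tsv", sep="\t", index=False)
    return results


def stage_subtype(
    config: PipelineConfig, table: AbundanceTable | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    table = table if table is not None else _load_processed(config)
    cases = table.group_samples("case")
    case_table = table.subset_samples(cases)
    result = sub_mod.consensus_cluster(
        case_table,
        k_max=config.k_max,
        reps=config.consensus_reps,
        subsample_frac=config.subsample_frac,
        seed=config.seed,
        k_override=config.k_override,
    )
    labels = result.labels_for()
    markers = sub_mod.subtype_markers(case_table, labels, fdr_cut=config.subtype_fdr)
    out = _out(config)
    labels.rename("subtype").to_frame().to_csv(out / "subtype_labels.tsv", sep="\t", index_label="sample")
    result.consensus_matrices[result.chosen_k].round(6).to_csv(out / "consensus_matrix.tsv", sep="\t")
    markers.round(10).to_csv(out / "subtype_markers.tsv", sep="\t", index_label="protein")
    markers.attrs["chosen_k"] = result.chosen_k
    return labels, markers


def stage_survival(
    config: PipelineConfig,
    labels: pd.Series | None = None,
    markers: pd.DataFrame | None = None,
) -> dict:
    out = _out(config)
    if labels is None:
        path = _require(out / "subtype_labels.tsv", "subtype labels")
        labels = pd.read_csv(path, sep="\t", index_col="sample")["subtype"]
    report: dict = {}

    if config.survival:
        surv = read_survival(_require(config.survival, "survival"))
        surv = surv[surv["sample"].isin(labels.index)].copy()
        surv["group"] = surv["sample"].map(labels).astype(str)
        if surv["group"].nunique() == 2 and surv["event"].sum() > 0:
            chi2, p = surv_mod.logrank_test(surv)
            report["discovery_logrank_chi2"] = round(chi2, 6)
            report["discovery_logrank_p"] = round(p, 6)
            for g in sorted(surv["group"].unique()):
                surv_mod.km_curve(surv, g).round(6).to_csv(
                    out / f"km_discovery_{g}.tsv", sep="\t", index=False
                )

    if config.mirror_abundance and markers is not None:
        mirror = read_abundance(
            _require(config.mirror_abundance, "mirror abundance"),
            _require(Path(config.mirror_abundance).with_name("mirror_design.tsv"), "mirror design"),
        )
        marker_ids = list(markers.index[markers["is_marker"]])
        if len(marker_ids) >= 10:
            ext_labels, _ = sub_mod.validate_signature(
                mirror, marker_ids, k=2, reps=max(config.consensus_reps // 4, 50), seed=config.seed
            )
            ext_labels.rename("subtype").to_frame().to_csv(
                out / "mirror_subtype_labels.tsv", sep="\t", index_label="sample"
            )
            if config.mirror_survival:
                msurv = read_survival(_require(config.mirror_survival, "mirror survival"))
                msurv = msurv[msurv["sample"].isin(ext_labels.index)].copy()
                msurv["group"] = msurv["sample"].map(ext_labels).astype(str)
                chi2, p = surv_mod.logrank_test(msurv)
                report["mirror_logrank_chi2"] = round(chi2, 6)
                report["mirror_logrank_p"] = round(p, 6)
    (out / "survival_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and write the JSON manifest."""
    config.validate()
    out = _out(config)
    table = stage_preprocess(config)
    de_results = stage_de(config, table)
    links = stage_dce(config, table)
    unified, stars = stage_network(config, de_results, links)
    filtered = stars.attrs["filtered"]
    enrich_results = {}
    if config.gmt:
        enrich_results = stage_enrich(config, de_results, links, unified)
    labels, markers = stage_subtype(config, table)
    surv_report = stage_survival(config, labels, markers)

    dcps = dce_mod.find_dcps(links, qth=config.dcp_fdr)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": {
            "proteins_retained": len(table.proteins),
            "samples": len(table.samples),
            "de_up": int((de_results["status"] == "up").sum()),
            "de_down": int((de_results["status"] == "down").sum()),
            "links_tested": int(len(links)),
            "dcl": int(links["is_dcl"].sum()),
            "dcp": int(dcps["is_dcp"].sum()),
            "stars_scored": int(len(stars)),
            "stars_significant": int(stars["significant"].sum()),
            "stars_retained": int(filtered["retained"].sum()),
            "unified_nodes": unified.number_of_nodes(),
            "unified_edges": unified.number_of_edges(),
            "chosen_k": int(markers.attrs["chosen_k"]),
            "subtype_markers": int(markers["is_marker"].sum()),
            "enriched_sets": {k: int((v["fdr"] < config.enrich_fdr).sum()) for k, v in enrich_results.items()},
        },
        "survival": surv_report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def run_stage(stage: str, config: PipelineConfig) -> object:
    """Run one named stage; raises on unknown names or missing inputs."""
    dispatch = {
        "preprocess": stage_preprocess,
        "de": stage_de,
        "dce": stage_dce,
        "network": stage_network,
        "enrich": stage_enrich,
        "subtype": stage_subtype,
        "survival": stage_survival,
    }
    if stage not in dispatch:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    config.validate()
    return dispatch[stage](config)
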