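"""Synthetic data with known planted structure.

Emulates a two-group label-free proteomics study -- 30 tumor and 22
control tissues by default -- so that every downstream stage (moderated
differential expression, differential co-expression, network
integration, subtype discovery, survival comparison) can be scored
against a recoverable ground truth.

What is planted
---------------
* per-protein baseline log2 abundances, normal with protein-specific
  mean and spread;
* a set of differentially expressed proteins shifted by +-de_log2fc in
  the case group;
* co-expression modules built from a shared latent factor,
  x = sqrt(rho)*f + sqrt(1-rho)*eps, giving expected pairwise
  correlation rho_case in cases and rho_ctrl in controls; module members
  form cliques in the emitted interaction network, on top of a
  preferential-attachment background whose heavy-tailed degrees resemble
  curated PPI resources;
* missingness as a mixture of uniform dropout and a logistic
  abundance-dependent (MNAR) component, mimicking low-intensity dropout
  in label-free quantification;
* a two-subtype split of the case group with shifted marker proteins and
  exponential survival times whose hazard differs between subtypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .data import CASE, CONTROL, AbundanceTable, SyntheticTruth, canonical_pair

__all__ = ["SyntheticConfig", "generate_dataset", "generate_mrna_mirror", "make_gene_sets"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_case: int = 30
    n_ctrl: int = 22
    n_proteins: int = 2000

    # differential expression
    de_fraction: float = 0.08
    de_log2fc: float = 1.5

    # planted co-expression modules
    n_modules: int = 1
    module_size: int = 10
    r_case: float = 0.9
    r_ctrl: float = 0.0
    de_on_modules: bool = True  # module members are also DE (dysregulated modules)

    # missingness
    missing_fraction: float = 0.10
    mnar_weight: float = 0.5

    # subtypes inside the case group
    n_subtypes: int = 2
    subtype_prop: float = 0.6  # fraction of cases in subtype 1 (18/30 of the design)
    subtype_effect: float = 1.5
    n_markers: int = 125

    # survival
    survival_hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 40.0  # events per month in subtype 1
    followup_max: float = 60.0  # uniform censoring horizon, months

    # abundance scale
    baseline_mean: float = 25.0
    baseline_mean_sd: float = 3.0
    protein_sd_median: float = 0.6
    protein_sd_log_sd: float = 0.3

    # interaction network background
    ppi_attachment: int = 2  # preferential-attachment edges per new node

    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_case, self.n_ctrl, self.n_proteins, self.module_size, self.n_subtypes)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for name in ("de_fraction", "missing_fraction", "mnar_weight", "subtype_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("r_case", "r_ctrl"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("planted modules do not fit into the protein universe")

    def to_dict(self) -> dict:
        return asdict(self)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n_case: int, n_ctrl: int) -> tuple[list[str], list[str]]:
    cases = [f"T{i:02d}" for i in range(1, n_case + 1)]
    ctrls = [f"N{i:02d}" for i in range(1, n_ctrl + 1)]
    return cases, ctrls


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[AbundanceTable, nx.Graph, SyntheticTruth, pd.DataFrame]:
    """Generate the full synthetic study.

    Returns the abundance table (with missing values), the interaction
    network containing the planted module cliques, the planted truth, and
    a survival table for the case samples. Fixed seed => byte-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p, n1, n2 = config.n_proteins, config.n_case, config.n_ctrl
    n = n1 + n2
    proteins = _protein_ids(p)
    cases, ctrls = _sample_ids(n1, n2)
    samples = cases + ctrls
    case_cols = np.arange(n1)
    ctrl_cols = np.arange(n1, n)

    # --- baseline abundances -------------------------------------------------
    mu = rng.normal(config.baseline_mean, config.baseline_mean_sd, size=p)
    sigma = np.exp(rng.normal(math.log(config.protein_sd_median), config.protein_sd_log_sd, size=p))
    eps = rng.standard_normal((p, n))
    x = eps.copy()

    # --- planted modules (latent factor within each group) -------------------
    module_assignments: dict[str, int] = {}
    module_edges: set[tuple[str, str]] = set()
    module_rows: list[np.ndarray] = []
    pool = rng.permutation(p)
    cursor = 0
    for mod in range(config.n_modules):
        rows = np.sort(pool[cursor : cursor + config.module_size])
        cursor += config.module_size
        module_rows.append(rows)
        for i, ri in enumerate(rows):
            module_assignments[proteins[ri]] = mod
            for rj in rows[i + 1 :]:
                module_edges.add(canonical_pair(proteins[ri], proteins[rj]))
        for cols, rho in ((case_cols, config.r_case), (ctrl_cols, config.r_ctrl)):
            f = rng.standard_normal(len(cols))
            x[np.ix_(rows, cols)] = (
                math.sqrt(abs(rho)) * np.sign(rho) * f[None, :]
                + math.sqrt(1.0 - abs(rho)) * eps[np.ix_(rows, cols)]
            )

    values = mu[:, None] + sigma[:, None] * x

    # --- planted differential expression -------------------------------------
    module_idx = np.concatenate(module_rows) if module_rows else np.array([], dtype=int)
    non_module = np.setdiff1d(np.arange(p), module_idx)
    n_de = int(round(config.de_fraction * p))
    de_rows = rng.choice(non_module, size=min(n_de, non_module.size), replace=False)
    signs = rng.choice([-1, 1], size=de_rows.size)
    de_proteins = {proteins[r]: int(s) for r, s in zip(de_rows, signs)}
    if config.de_on_modules:
        for mod, rows in enumerate(module_rows):
            sign = 1 if mod % 2 == 0 else -1
            for r in rows:
                de_proteins[proteins[r]] = sign
    if config.de_log2fc != 0 and de_proteins:
        row_of = {prot: i for i, prot in enumerate(proteins)}
        rows = np.array([row_of[prot] for prot in de_proteins])
        shift = np.array(list(de_proteins.values()), dtype=float)
        values[np.ix_(rows, case_cols)] += (shift * config.de_log2fc)[:, None]

    # --- subtypes inside the case group --------------------------------------
    n_sub1 = int(round(config.subtype_prop * n1))
    order = rng.permutation(n1)
    subtype_labels = {cases[i]: (1 if rank < n_sub1 else 2) for rank, i in enumerate(order)}
    marker_pool = np.setdiff1d(non_module, de_rows)
    marker_rows = rng.choice(marker_pool, size=min(config.n_markers, marker_pool.size), replace=False)
    marker_signs = rng.choice([-1, 1], size=marker_rows.size)
    marker_proteins = {proteins[r] for r in marker_rows}
    sub2_cols = np.array([i for i in case_cols if subtype_labels[cases[i]] == 2])
    if config.n_subtypes >= 2 and sub2_cols.size:
        values[np.ix_(marker_rows, sub2_cols)] += (marker_signs * config.subtype_effect)[:, None]

    # --- missingness: MCAR + logistic MNAR -----------------------------------
    if config.missing_fraction > 0:
        flat = values.ravel()
        center = np.quantile(flat, 0.2)
        scale = max(np.std(flat), 1e-9)
        mnar_shape = 1.0 / (1.0 + np.exp((values - center) / (0.5 * scale)))
        mnar = config.missing_fraction * config.mnar_weight * mnar_shape / mnar_shape.mean()
        mcar = config.missing_fraction * (1.0 - config.mnar_weight)
        prob = np.clip(mcar + mnar, 0.0, 0.95)
        mask = rng.random(values.shape) < prob
        values = np.where(mask, np.nan, values)

    frame = pd.DataFrame(values, index=proteins, columns=samples)
    design = pd.Series([CASE] * n1 + [CONTROL] * n2, index=samples)
    table = AbundanceTable(values=frame, design=design)

    # --- interaction network --------------------------------------------------
    network = nx.barabasi_albert_graph(p, config.ppi_attachment, seed=int(rng.integers(2**31)))
    network = nx.relabel_nodes(network, {i: proteins[i] for i in range(p)})
    network.add_edges_from(module_edges)
    network.remove_edges_from(nx.selfloop_edges(network))

    truth = SyntheticTruth(
        de_proteins=de_proteins,
        module_assignments=module_assignments,
        module_edges=module_edges,
        subtype_labels=subtype_labels,
        marker_proteins=marker_proteins,
    )

    survival = _survival_table(
        list(subtype_labels.items()), config.survival_hazard_ratio, config.baseline_hazard,
        config.followup_max, rng,
    )
    return table, network, truth, survival


def _survival_table(labelled_samples, hazard_ratio, baseline_hazard, followup_max, rng) -> pd.DataFrame:
    rows = []
    for sample, subtype in labelled_samples:
        rate = baseline_hazard * (hazard_ratio if subtype == 2 else 1.0)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, followup_max)
        rows.append(
            {
                "sample": sample,
                "time": round(min(t_event, t_cens), 3),
                "event": int(t_event <= t_cens),
                "group": f"subtype{subtype}",
            }
        )
    return pd.DataFrame(rows)


def generate_mrna_mirror(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    n_samples: int = 113,
    noise_sd: float = 1.0,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Independent "mRNA" validation cohort sharing the planted subtype axis.

    The mirror carries the subtype-marker genes with the same subtype
    shifts plus N(0, noise_sd) noise, a pool of uninformative background
    genes, and subtype-linked survival. Used to exercise cross-dataset
    signature validation.
    """
    if n_samples < 2 * config.n_subtypes:
        raise ValueError("need at least two samples per subtype")
    rng = np.random.default_rng(config.seed + 104729)
    markers = sorted(truth.marker_proteins)
    # marker shift directions need not match the discovery cohort; only the
    # shared subtype axis matters for signature validation
    signs = {m: int(s) for m, s in zip(markers, rng.choice([-1, 1], size=len(markers)))}

    background = [f"G{i:04d}" for i in range(1, 501)]
    genes = markers + background
    samples = [f"E{i:03d}" for i in range(1, n_samples + 1)]
    n_sub1 = int(round(config.subtype_prop * n_samples))
    order = rng.permutation(n_samples)
    subtype = {samples[i]: (1 if rank < n_sub1 else 2) for rank, i in enumerate(order)}

    values = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    sub2 = np.array([j for j, s in enumerate(samples) if subtype[s] == 2])
    for i, m in enumerate(markers):
        values[i, sub2] += signs[m] * config.subtype_effect
    if noise_sd > 0:
        values[: len(markers)] += rng.normal(0.0, noise_sd, size=(len(markers), n_samples))

    frame = pd.DataFrame(values, index=genes, columns=samples)
    design = pd.Series([CASE] * n_samples, index=samples)
    table = AbundanceTable(values=frame, design=design)
    survival = _survival_table(
        list(subtype.items()), config.survival_hazard_ratio, config.baseline_hazard,
        config.followup_max, rng,
    )
    return table, survival


def make_gene_sets(
    truth: SyntheticTruth,
    universe,
    n_decoys: int = 20,
    decoy_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Gene-set collection: one set per planted module plus random decoys."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, set[str]] = {}
    by_module: dict[int, set[str]] = {}
    for prot, mod in truth.module_assignments.items():
        by_module.setdefault(mod, set()).add(prot)
    for mod, members in sorted(by_module.items()):
        sets[f"planted_module_{mod}"] = members
    lo, hi = decoy_size_range
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        sets[f"decoy_{i:02d}"] = set(rng.choice(universe, size=size, replace=False))
    return sets
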