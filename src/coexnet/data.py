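"""Core data containers and plain-text readers/writers.

Everything the pipeline exchanges on disk is tab-separated text: the
abundance matrix (first column protein id, header row sample ids, empty
cell = missing value), the design table (sample, group), edge lists in
either a plain two-column or a HIPPIE-style six-column dialect, GMT gene
sets, and the survival table (sample, time, event[, group]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


@dataclass
class AbundanceTable:
    """Log2 protein abundance matrix with its two-group sample design.

    ``values`` is proteins x samples with NaN marking missing entries;
    ``design`` maps every sample id to a group label ("case"/"control",
    or subtype labels when the table is reused for within-tumor tests).
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        self.design = self.design.astype(str)
        if not self.values.index.is_unique:
            raise ValueError("duplicate protein identifiers")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample identifiers")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"design does not cover samples: {sorted(missing)[:5]}")
        self.design = self.design.loc[self.values.columns]

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def group_matrix(self, group: str) -> pd.DataFrame:
        return self.values[self.group_samples(group)]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, samples) -> "AbundanceTable":
        samples = list(samples)
        return AbundanceTable(self.values[samples].copy(), self.design.loc[samples].copy())


# ---------------------------------------------------------------------------
# abundance / design / survival tables


def write_abundance(table: AbundanceTable, abundance_path, design_path) -> None:
    df = table.values.copy()
    df.index.name = "protein"
    df.to_csv(abundance_path, sep="\t", na_rep="")
    design = table.design.rename("group").to_frame()
    design.index.name = "sample"
    design.to_csv(design_path, sep="\t")


def read_abundance(abundance_path, design_path) -> AbundanceTable:
    values = pd.read_csv(abundance_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)["group"]
    return AbundanceTable(values=values, design=design)


def write_survival(survival: pd.DataFrame, path) -> None:
    survival.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return df


# ---------------------------------------------------------------------------
# edge lists


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_hippie_edge_list(edges, path, confidence=None) -> None:
    """Write a HIPPIE-dialect file: geneA, idA, geneB, idB, confidence, evidence."""
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(edges):
            score = 0.9 if confidence is None else confidence[i]
            fh.write(f"{a}\t{a}_id\t{b}\t{b}_id\t{score:.3f}\texperiments\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member set}."""
    from gseapy.parser import read_gmt

    raw = read_gmt(str(path))
    return {name: set(members) for name, members in raw.items()}


# ---------------------------------------------------------------------------
# identifier lists and truth JSON


def read_id_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_id_list(ids, path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset.

    de_proteins maps each planted differentially expressed protein to its
    sign (+1 up in cases, -1 down); module_assignments maps proteins to
    planted co-expression module ids; module_edges is the set of planted
    within-module pairs (canonical order); subtype_labels maps each case
    sample to its planted subtype; marker_proteins are the subtype-marker
    identifiers.
    """

    de_proteins: dict[str, int]
    module_assignments: dict[str, int]
    module_edges: set[tuple[str, str]]
    subtype_labels: dict[str, int]
    marker_proteins: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "de_proteins": self.de_proteins,
            "module_assignments": self.module_assignments,
            "module_edges": sorted([list(e) for e in self.module_edges]),
            "subtype_labels": self.subtype_labels,
            "marker_proteins": sorted(self.marker_proteins),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_proteins={k: int(v) for k, v in payload["de_proteins"].items()},
            module_assignments={k: int(v) for k, v in payload["module_assignments"].items()},
            module_edges={tuple(e) for e in payload["module_edges"]},
            subtype_labels={k: int(v) for k, v in payload["subtype_labels"].items()},
            marker_proteins=set(payload["marker_proteins"]),
        )


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered protein pair stored lexicographically."""
    return (a, b) if a <= b else (b, a)
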