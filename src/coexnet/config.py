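"""Pipeline configuration: paths, thresholds, replicate counts, seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Threshold defaults are the analysis defaults used throughout:
    missingness filter 0.40; DE at FDR < 0.1 with fold change > 1.5;
    DCL criteria |r| > 0.5 / FDR < 0.1 and |dr| > 0.5 / FDR < 0.1; local
    subnetworks at FDR < 0.1 then Holm-adjusted DC-enrichment < 0.1;
    subtype markers at FDR < 0.001; 1000 consensus subsamples up to
    k_max = 6; 10,000 calibration permutations for the local scan.
    """

    # inputs (None = stage not run / produced by simulate)
    abundance: str | None = None
    design: str | None = None
    ppi: str | None = None
    gmt: str | None = None
    survival: str | None = None
    disease_genes: str | None = None
    druggable: str | None = None
    mirror_abundance: str | None = None
    mirror_survival: str | None = None
    outdir: str = "coexnet_out"

    # preprocessing
    max_missing: float = 0.40
    knn_k: int = 10

    # differential expression
    de_fdr: float = 0.1
    fc_cut: float = 1.5

    # differential co-expression
    rth: float = 0.5
    qth: float = 0.1
    r_diffth: float = 0.5
    q_diffth: float = 0.1
    diff_fdr_scope: str = "coexpressed"
    dcp_fdr: float = 0.1

    # network integration
    lean_fdr: float = 0.1
    lean_perm: int = 10_000
    star_alpha: float = 0.1
    star_background: str = "tested"

    # enrichment
    enrich_fdr: float = 0.1

    # subtyping / survival
    subtype_fdr: float = 0.001
    consensus_reps: int = 1000
    k_max: int = 6
    subsample_frac: float = 0.8
    k_override: int | None = 2

    seed: int = 0

    def validate(self) -> None:
        for name in ("max_missing", "de_fdr", "qth", "q_diffth", "lean_fdr",
                     "star_alpha", "subtype_fdr", "enrich_fdr", "subsample_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fc_cut < 1.0:
            raise ValueError("fc_cut is a ratio and must be >= 1")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    _PATH_FIELDS = (
        "abundance", "design", "ppi", "gmt", "survival", "disease_genes",
        "druggable", "mirror_abundance", "mirror_survival", "outdir",
    )

    def config_hash(self) -> str:
        """Hash of the analysis parameters only (paths excluded), so the
        same analysis on the same data hashes identically anywhere."""
        payload = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
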