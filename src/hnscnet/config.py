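"""Configuration objects shared across the pipeline.

All tunables live in small dataclasses that round-trip losslessly to
YAML/JSON, so a run is fully described by one config file plus a seed.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

STAGES = ("I", "II", "III", "IVa", "IVb")

#: Tumor-stage mix modelled on a large head-and-neck carcinoma cohort
#: (stage IV dominates; IVb is rare, which exercises the minimum-group-size
#: exclusion in the stage-level analysis).
DEFAULT_STAGE_PROPORTIONS = {
    "I": 0.042,
    "II": 0.193,
    "III": 0.211,
    "IVa": 0.534,
    "IVb": 0.020,
}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    The generator emulates a tumor/control bulk RNA-seq cohort: negative
    binomial counts with library-size variation and planted fold changes,
    a miRNA->target map in which down-regulated miRNAs preferentially
    target up-regulated genes, a scale-free interaction network with
    planted high-centrality nodes, and survival times whose hazard depends
    on the expression of designated prognostic miRNAs.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_tumor: int = 200
    n_control: int = 44
    stage_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROPORTIONS)
    )
    frac_de_genes: float = 0.1
    frac_de_mirnas: float = 0.2
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    libsize_log_sd: float = 0.2
    repression_enrichment: float = 5.0
    ba_attachment: int = 3
    hazard_log_hr: float = 1.0
    seed: int = 0
    # secondary knobs (defaults chosen once; see docs/methods.md)
    target_base_prob: float = 0.05
    n_planted_hubs: int = 5
    hub_boost: float = 10.0
    n_modules: int = 5
    n_prognostic: int = 1
    baseline_median: float = 100.0
    baseline_log_sd: float = 1.5
    baseline_hazard: float = 1e-3  # events per day at average expression
    stage_effect: float = 0.0  # extra per-stage log2FC slope for DE features

    def validate(self) -> "SimConfig":
        for name in ("n_genes", "n_mirnas", "n_tumor", "n_control"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        if set(self.stage_proportions) != set(STAGES):
            raise ConfigError(f"stage_proportions must cover stages {STAGES}")
        total = sum(self.stage_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"stage_proportions sum to {total}, expected 1")
        for name in ("frac_de_genes", "frac_de_mirnas"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.planted_log2fc <= 0:
            raise ConfigError("planted_log2fc must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.libsize_log_sd < 0:
            raise ConfigError("libsize_log_sd must be nonnegative")
        if self.repression_enrichment < 1:
            raise ConfigError("repression_enrichment must be >= 1")
        if self.ba_attachment < 1:
            raise ConfigError("ba_attachment must be a positive integer")
        if not 0 < self.target_base_prob < 1:
            raise ConfigError("target_base_prob must lie in (0, 1)")
        return self


@dataclass
class DEThresholds:
    """Selection thresholds for differential-expression calls.

    ``min_abs_fc_list`` is the looser cut used for the reported DEG list;
    ``min_abs_fc_network`` the stricter cut used to seed PPI networks;
    the miRNA volcano cut uses raw p by default (configurable).
    """

    adjp_max: float = 0.01
    min_abs_fc_list: float = 1.5
    min_abs_fc_network: float = 2.0
    mirna_volcano_fc: float = 2.0
    mirna_volcano_p: float = 1e-5
    mirna_use_adjusted_p: bool = False
    stage_min_n: int = 15

    def validate(self) -> "DEThresholds":
        if not 0 < self.adjp_max <= 1:
            raise ConfigError("adjp_max must lie in (0, 1]")
        for name in (
            "min_abs_fc_list",
            "min_abs_fc_network",
            "mirna_volcano_fc",
            "mirna_volcano_p",
            "stage_min_n",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        return self


@dataclass
class NullModelConfig:
    """Degree-preserving randomization settings for hub validation."""

    n_random: int = 1000
    swaps_per_edge: int = 10
    seed: int = 0

    def validate(self) -> "NullModelConfig":
        if self.n_random < 1:
            raise ConfigError("n_random must be >= 1")
        if self.swaps_per_edge < 1:
            raise ConfigError("swaps_per_edge must be >= 1")
        return self


@dataclass
class PipelineConfig:
    """End-to-end run description: inputs (or a synthesis directive),
    thresholds, and output location."""

    outdir: str = "hnscnet_out"
    seed: int = 0
    # Either synthesize inputs ...
    synthesize: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # ... or point at existing tables.
    gene_counts: Optional[str] = None
    mirna_counts: Optional[str] = None
    sample_metadata: Optional[str] = None
    target_map: Optional[str] = None
    ppi_edges: Optional[str] = None
    gene_sets: Optional[str] = None  # optional GMT
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    bipartite_multiplier: float = 2.0
    ppi_exp_min: float = 0.1
    ppi_db_min: float = 0.3
    string_scale: bool = False
    nulls: NullModelConfig = field(default_factory=NullModelConfig)
    survival_rule: str = "median"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.thresholds.validate()
        self.nulls.validate()
        if self.synthesize:
            self.sim.validate()
        else:
            required = (
                "gene_counts",
                "mirna_counts",
                "sample_metadata",
                "target_map",
                "ppi_edges",
            )
            for name in required:
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"{name} is required when synthesize=False")
                if not Path(path).exists():
                    raise ConfigError(f"{name} path does not exist: {path}")
        if self.survival_rule not in ("median", "tertile", "optimal"):
            raise ConfigError(f"unknown survival rule {self.survival_rule!r}")
        return self

    # -- round-trip --------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = DEThresholds(**d["thresholds"])
        if "nulls" in d and isinstance(d["nulls"], dict):
            d["nulls"] = NullModelConfig(**d["nulls"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
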