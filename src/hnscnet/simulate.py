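"""Synthetic cohort generator.

Produces every input the analysis consumes — count matrices with sample
metadata, a miRNA->target interaction map, a protein interaction edge
table, and survival outcomes — together with truth tables recording what
was planted, so downstream selection stages can be scored for recovery.

All randomness flows from ``SimConfig.seed`` through named child streams
(one per sub-generator), so regenerating with the same seed is
byte-identical regardless of which subset of generators is invoked.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import STAGES, ConfigError, SimConfig

# fixed tags for per-subgenerator seed streams
_STREAMS = {"gene": 1, "mirna": 2, "targets": 3, "ppi": 4, "survival": 5}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), _STREAMS[stream]))
    )


@dataclass
class CountMatrix:
    """Raw counts (features x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``condition``
    ("tumor"/"control"), ``stage`` (I..IVb for tumors, NA for controls),
    and optional ``time`` (days) / ``event`` (0/1) survival fields.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> "CountMatrix":
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns and sample metadata disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        tumors = self.samples["condition"] == "tumor"
        if self.samples.loc[tumors, "stage"].isna().any():
            raise ValueError("every tumor sample needs a stage")
        return self

    def tumor_ids(self) -> list:
        return list(self.samples.index[self.samples["condition"] == "tumor"])

    def control_ids(self) -> list:
        return list(self.samples.index[self.samples["condition"] == "control"])


@dataclass
class TruthTables:
    """Ground truth emitted alongside generated data.

    ``de_genes`` / ``de_mirnas`` map feature id -> signed planted log2 fold
    change; ``prognostic_mirnas`` map miRNA id -> hazard direction (+1 means
    higher expression, higher hazard); ``planted_hubs`` are nodes given
    elevated attachment in the network generator. ``feature_ids`` records
    the full generated universe so maps can be drawn from it.
    """

    de_genes: dict = field(default_factory=dict)
    de_mirnas: dict = field(default_factory=dict)
    prognostic_mirnas: dict = field(default_factory=dict)
    planted_hubs: set = field(default_factory=set)
    feature_ids: dict = field(default_factory=dict)  # kind -> list of ids

    def de_directions(self, kind: str) -> pd.Series:
        table = self.de_genes if kind == "gene" else self.de_mirnas
        return pd.Series(
            {f: ("up" if lfc > 0 else "down") for f, lfc in table.items()},
            dtype=object,
        )


def _feature_ids(kind: str, n: int) -> list:
    prefix = "gene" if kind == "gene" else "hsa-mir-"
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(config: SimConfig) -> tuple[list, list]:
    tumors = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    controls = [f"C{i:04d}" for i in range(1, config.n_control + 1)]
    return tumors, controls


def simulate_counts(config: SimConfig, feature_kind: str) -> tuple[CountMatrix, TruthTables]:
    """Draw a raw-count matrix for genes or miRNAs.

    Counts are negative binomial with mean ``baseline * sizefactor *
    2**(log2FC * is_tumor)`` and common dispersion ``nb_dispersion``;
    per-sample size factors are log-normal(0, ``libsize_log_sd``). Exactly
    ``round(frac_de * n_features)`` features carry a nonzero planted
    log2FC, half positive and half negative (ties to positive). Tumor
    samples receive stage labels by ``stage_proportions``.
    """
    config.validate()
    if feature_kind not in ("gene", "mirna"):
        raise ConfigError(f"feature_kind must be 'gene' or 'mirna', got {feature_kind!r}")
    rng = _rng(config, feature_kind)

    n_feat = config.n_genes if feature_kind == "gene" else config.n_mirnas
    frac_de = config.frac_de_genes if feature_kind == "gene" else config.frac_de_mirnas
    ids = _feature_ids(feature_kind, n_feat)
    tumors, controls = _sample_ids(config)
    sample_ids = tumors + controls
    n_samples = len(sample_ids)

    # planted differential expression: exact count, balanced signs
    n_de = int(round(frac_de * n_feat))
    de_idx = np.sort(rng.choice(n_feat, size=n_de, replace=False))
    n_pos = (n_de + 1) // 2  # ties to positive
    signs = np.concatenate([np.ones(n_pos), -np.ones(n_de - n_pos)])
    rng.shuffle(signs)
    lfc = np.zeros(n_feat)
    lfc[de_idx] = signs * config.planted_log2fc

    baseline = rng.lognormal(np.log(config.baseline_median), config.baseline_log_sd, n_feat)
    size_factors = rng.lognormal(0.0, config.libsize_log_sd, n_samples)

    stages = list(config.stage_proportions)
    probs = np.array([config.stage_proportions[s] for s in stages])
    stage_labels = rng.choice(stages, size=config.n_tumor, p=probs / probs.sum())

    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_control)
    # optional per-stage slope on the planted effect (0 by default)
    stage_rank = {s: i for i, s in enumerate(STAGES)}
    effect = np.ones(n_samples)
    if config.stage_effect != 0:
        mid = (len(STAGES) - 1) / 2.0
        tumor_scale = np.array(
            [1.0 + config.stage_effect * (stage_rank[s] - mid) for s in stage_labels]
        )
        effect[: config.n_tumor] = tumor_scale
    log2fc_per_sample = np.outer(lfc, is_tumor * effect)  # feat x sample
    mean = baseline[:, None] * size_factors[None, :] * np.exp2(log2fc_per_sample)

    alpha = config.nb_dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mean))

    samples = pd.DataFrame(
        {
            "condition": ["tumor"] * config.n_tumor + ["control"] * config.n_control,
            "stage": list(stage_labels) + [pd.NA] * config.n_control,
            "time": np.nan,
            "event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="feature"), columns=sample_ids),
        samples=samples,
    ).validate()

    truth = TruthTables(feature_ids={feature_kind: ids})
    de_map = {ids[i]: float(lfc[i]) for i in de_idx}
    if feature_kind == "gene":
        truth.de_genes = de_map
    else:
        truth.de_mirnas = de_map
        # designate prognostic miRNAs among planted up-regulated ones
        up = sorted(f for f, v in de_map.items() if v > 0) or sorted(de_map)
        chosen = up[: config.n_prognostic]
        truth.prognostic_mirnas = {m: +1 for m in chosen}
    return cm, truth


def simulate_target_map(
    config: SimConfig, gene_truth: TruthTables, mirna_truth: TruthTables
) -> pd.DataFrame:
    """Draw a miRNA->gene target table.

    Every (miRNA, gene) pair is included with base probability
    ``target_base_prob``; for pairs of a down-regulated miRNA and an
    up-regulated gene the odds are multiplied by ``repression_enrichment``,
    planting the repression signal the integration stage looks for.
    """
    config.validate()
    genes = gene_truth.feature_ids.get("gene", [])
    mirnas = mirna_truth.feature_ids.get("mirna", [])
    if not genes or not mirnas:
        raise ConfigError("empty feature universe for target map")
    rng = _rng(config, "targets")

    p0 = config.target_base_prob
    probs = np.full((len(mirnas), len(genes)), p0)
    odds_enriched = p0 / (1 - p0) * config.repression_enrichment
    p_enriched = odds_enriched / (1 + odds_enriched)
    down_m = [i for i, m in enumerate(mirnas) if mirna_truth.de_mirnas.get(m, 0) < 0]
    up_g = [j for j, g in enumerate(genes) if gene_truth.de_genes.get(g, 0) > 0]
    if down_m and up_g:
        probs[np.ix_(down_m, up_g)] = p_enriched

    draws = rng.random(probs.shape) < probs
    mi, gi = np.nonzero(draws)
    return pd.DataFrame(
        {
            "mirna_id": [mirnas[i] for i in mi],
            "gene_id": [genes[j] for j in gi],
            "source": "simulated",
        }
    )


def _ba_module(nodes: list, m: int, rng: np.random.Generator) -> list[tuple]:
    """Preferential-attachment graph over ``nodes`` in the given arrival
    order: initial clique of m+1, then m degree-weighted edges per node."""
    seed_nodes = nodes[: m + 1]
    rest = nodes[m + 1 :]
    edges = [(u, v) for i, u in enumerate(seed_nodes) for v in seed_nodes[:i]]
    present = list(seed_nodes)
    warr = np.full(len(present), float(m))  # clique degrees
    for u in rest:
        targets_idx = rng.choice(len(present), size=m, replace=False, p=warr / warr.sum())
        for ti in targets_idx:
            edges.append((u, present[ti]))
            warr[ti] += 1.0
        present.append(u)
        warr = np.append(warr, float(m))
    return edges


def simulate_ppi(
    config: SimConfig,
    gene_truth: Optional[TruthTables] = None,
    core_genes: Optional[Iterable] = None,
) -> tuple[pd.DataFrame, set]:
    """Draw a modular scale-free interaction edge table with planted hubs.

    The graph is grown over the ``core_genes`` node set (default: the
    planted DE genes when truth is supplied, else the full gene universe);
    interaction density in real interactomes concentrates among
    disease-module genes, so restricting the dense core to DE genes keeps
    the DEG-induced subnetwork connected the way curated networks are.

    Topology: the non-hub core is partitioned into ``n_modules``
    preferential-attachment modules (a single plain scale-free graph when
    no hubs are planted, so ``ba_attachment=1`` yields a tree). Each
    planted hub is wired as an inter-module connector with total degree
    ~``hub_boost``-fold the ``ba_attachment`` edges an ordinary node
    brings, its neighbors drawn degree-weighted from every module. Connectors
    therefore carry high degree, betweenness, centroid and bridging
    simultaneously — the signature the composite hub rule looks for.
    Each edge gets independent uniform [0, 1] "experimental" and
    "database" channel scores.

    Returns the edge table and the set of planted hub ids (also written
    into ``gene_truth.planted_hubs`` when truth is supplied).
    """
    config.validate()
    rng = _rng(config, "ppi")
    if core_genes is not None:
        core = list(core_genes)
    elif gene_truth is not None and gene_truth.de_genes:
        core = sorted(gene_truth.de_genes)
    elif gene_truth is not None:
        core = list(gene_truth.feature_ids.get("gene", []))
    else:
        raise ConfigError("simulate_ppi needs gene_truth or core_genes")
    m = config.ba_attachment
    if len(core) < m + 2 + config.n_planted_hubs:
        raise ConfigError("core gene set too small for preferential attachment")

    # hubs are planted among disease (DE) genes when truth is available, so
    # they are present in the DEG-seeded network where hubs are selected
    candidates = sorted(set(core) & set(gene_truth.de_genes)) if (
        gene_truth is not None and gene_truth.de_genes
    ) else list(core)
    n_hubs = min(config.n_planted_hubs, len(candidates))
    hubs = {str(v) for v in rng.choice(candidates, size=n_hubs, replace=False)}
    members = [str(v) for v in rng.permutation([c for c in core if str(c) not in hubs])]

    if n_hubs == 0:
        k = 1
    else:
        k = max(1, min(config.n_modules, len(members) // (m + 2)))
    modules = [members[i::k] for i in range(k)]
    edges: list[tuple] = []
    for module in modules:
        edges.extend(_ba_module(module, m, rng))

    # wire each planted hub across all modules, degree-weighted
    if n_hubs:
        deg: dict = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        per_module = max(1, int(round(config.hub_boost * m / k)))
        for h in sorted(hubs):
            for module in modules:
                w = np.array([deg[v] for v in module], dtype=float)
                size = min(per_module, len(module))
                targets_idx = rng.choice(len(module), size=size, replace=False, p=w / w.sum())
                edges.extend((h, module[ti]) for ti in targets_idx)

    exp_scores = rng.random(len(edges))
    db_scores = rng.random(len(edges))
    table = pd.DataFrame(
        {
            "gene_a": [e[0] for e in edges],
            "gene_b": [e[1] for e in edges],
            "experimental_score": exp_scores,
            "database_score": db_scores,
        }
    )
    if gene_truth is not None:
        gene_truth.planted_hubs = set(hubs)
    return table, set(hubs)


def simulate_survival(
    config: SimConfig, mirna_counts: CountMatrix, mirna_truth: TruthTables
) -> pd.DataFrame:
    """Attach exponential survival outcomes to the tumor samples.

    The hazard is ``baseline_hazard * exp(hazard_log_hr * z * direction)``
    where ``z`` is the standardized log2 library-size-normalized expression
    of the designated prognostic miRNA(s). Censoring is independent uniform
    on [0, T_max] with T_max = 3.1 / baseline_hazard, giving roughly 30%
    censoring at average expression. Updates ``mirna_counts.samples`` in
    place and returns the (time, event) frame for tumor samples.
    """
    config.validate()
    rng = _rng(config, "survival")
    tumors = mirna_counts.tumor_ids()
    if not tumors:
        raise ConfigError("no tumor samples to simulate survival for")

    counts = mirna_counts.counts[tumors]
    libsize = counts.sum(axis=0).astype(float)
    cpm = counts / libsize * 1e6

    log_hr = np.zeros(len(tumors))
    for mirna, direction in mirna_truth.prognostic_mirnas.items():
        if mirna not in cpm.index:
            continue
        x = np.log2(cpm.loc[mirna].to_numpy() + 1.0)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        log_hr += config.hazard_log_hr * direction * z

    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_max = 3.1 / config.baseline_hazard
    t_cens = rng.uniform(0.0, t_max, size=len(tumors))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    mirna_counts.samples.loc[tumors, "time"] = time
    mirna_counts.samples.loc[tumors, "event"] = event
    return pd.DataFrame({"time": time, "event": event}, index=pd.Index(tumors, name="sample_id"))


def simulate_all(config: SimConfig) -> dict:
    """Run every sub-generator; returns a dict of all tables and truth."""
    gene_cm, gene_truth = simulate_counts(config, "gene")
    mirna_cm, mirna_truth = simulate_counts(config, "mirna")
    target_map = simulate_target_map(config, gene_truth, mirna_truth)
    # the interactome's dense core covers the disease-relevant genes: the
    # planted DE genes plus genes strongly targeted by DE miRNAs, so the
    # DEG network and both selected-target networks are all non-degenerate
    sub = target_map[target_map["mirna_id"].isin(set(mirna_truth.de_mirnas))]
    indeg = sub.groupby("gene_id").size()
    strong = set(indeg[indeg >= 2 * indeg.mean()].index) if len(indeg) else set()
    core = sorted(set(gene_truth.de_genes) | strong)
    if len(core) < config.ba_attachment + 2 + config.n_planted_hubs:
        core = gene_truth.feature_ids["gene"]  # global-null fallback
    ppi_edges, hubs = simulate_ppi(config, gene_truth, core_genes=core)
    survival = simulate_survival(config, mirna_cm, mirna_truth)
    # survival metadata applies to the cohort, not one assay
    gene_cm.samples.loc[survival.index, ["time", "event"]] = survival[["time", "event"]].to_numpy()
    truth = TruthTables(
        de_genes=gene_truth.de_genes,
        de_mirnas=mirna_truth.de_mirnas,
        prognostic_mirnas=mirna_truth.prognostic_mirnas,
        planted_hubs=hubs,
        feature_ids={**gene_truth.feature_ids, **mirna_truth.feature_ids},
    )
    return {
        "gene_counts": gene_cm,
        "mirna_counts": mirna_cm,
        "target_map": target_map,
        "ppi_edges": ppi_edges,
        "survival": survival,
        "truth": truth,
    }
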