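"""End-to-end orchestration.

Runs (optionally) synthesis, then differential expression, bipartite
miRNA-target networks, PPI assembly (for the DEG set and each class's
selected targets), the centrality suite, hub selection with null-model
validation, the targeting-count contrast, enrichment (when gene sets are
supplied) and miRNA-stratified survival. Every stage writes its tables
under the output directory and records row/node/edge counts in a manifest;
empty-input conditions skip the stage and are recorded, never silently
passed.
"""
from __future__ import annotations

import hashlib
import logging
import time as _time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import bipartite as bp
from . import centrality as ct
from . import diffexpr as de
from . import integration as integ
from . import io as hio
from . import nullmodels as nm
from . import ppi as ppim
from . import simulate as sim
from . import survival as sv
from .config import PipelineConfig

log = logging.getLogger("hnscnet")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import networkx
    import scipy

    from . import __version__

    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "hnscnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "stages": {},
        "skipped": [],
    }
    t0 = _time.time()

    def stage_done(name, **counts):
        manifest["stages"][name] = {**counts, "elapsed_s": round(_time.time() - t0, 3)}

    # -- inputs -------------------------------------------------------------
    truth = None
    if config.synthesize:
        simcfg = config.sim
        simcfg.seed = config.seed
        data = sim.simulate_all(simcfg)
        gene_cm, mirna_cm = data["gene_counts"], data["mirna_counts"]
        target_map, ppi_edges = data["target_map"], data["ppi_edges"]
        truth = data["truth"]
        hio.write_counts(gene_cm, outdir / "gene_counts.tsv", outdir / "sample_metadata.tsv")
        hio.write_counts(mirna_cm, outdir / "mirna_counts.tsv", outdir / "mirna_sample_metadata.tsv")
        hio.write_table(target_map, outdir / "target_map.tsv", index=False)
        hio.write_table(ppi_edges, outdir / "ppi_edges.tsv", index=False)
        hio.write_truth(truth, outdir / "truth.tsv")
    else:
        gene_cm = hio.read_counts(config.gene_counts, config.sample_metadata)
        mirna_cm = hio.read_counts(config.mirna_counts, config.sample_metadata)
        target_map = hio.read_target_map(config.target_map)
        ppi_edges = hio.read_ppi_edges(config.ppi_edges)
        manifest["input_digests"] = {
            name: _digest(Path(getattr(config, name)))
            for name in ("gene_counts", "mirna_counts", "sample_metadata", "target_map", "ppi_edges")
        }
    stage_done("inputs", genes=len(gene_cm.counts), mirnas=len(mirna_cm.counts),
               samples=gene_cm.counts.shape[1], target_pairs=len(target_map),
               ppi_edge_rows=len(ppi_edges))

    # -- differential expression -------------------------------------------
    th = config.thresholds
    gene_norm = de.median_of_ratios(gene_cm.counts)
    mirna_norm = de.median_of_ratios(mirna_cm.counts)
    gene_table = de.de_table(gene_cm, gene_norm, th)
    mirna_table = de.de_table(mirna_cm, mirna_norm, th)
    hio.write_table(gene_table, outdir / "de_genes.tsv")
    hio.write_table(mirna_table, outdir / "de_mirnas.tsv")
    hio.write_table(de.volcano_export(mirna_table, th, "mirna"), outdir / "mirna_volcano.tsv")

    deg_list = de.apply_thresholds(gene_table, th, "gene_list")
    deg_network = de.apply_thresholds(gene_table, th, "gene_network")
    de_mirnas = de.apply_thresholds(mirna_table, th, "mirna")
    hio.write_table(deg_list, outdir / "deg_list.tsv")
    hio.write_table(deg_network, outdir / "deg_network_seed.tsv")
    hio.write_table(de_mirnas, outdir / "de_mirnas_selected.tsv")
    stage_done("diffexpr", deg_list=len(deg_list), deg_network=len(deg_network),
               de_mirnas_up=int((de_mirnas["direction"] == "up").sum()),
               de_mirnas_down=int((de_mirnas["direction"] == "down").sum()))

    # -- bipartite networks --------------------------------------------------
    up_net = down_net = None
    selected_targets = {"up": set(), "down": set()}
    if de_mirnas.empty:
        manifest["skipped"].append("bipartite: no DE miRNAs")
    else:
        up_net, down_net = bp.build_bipartite(de_mirnas["direction"], target_map)
        if not up_net.edges and not down_net.edges:
            manifest["skipped"].append("bipartite: no DE miRNA has any target")
            up_net = down_net = None
        else:
            def _select(net):
                if net.mirnas or net.genes:
                    return bp.rank_and_select(net, config.bipartite_multiplier)
                return None

            sel_up, sel_down = _select(up_net), _select(down_net)
            up_spec, down_spec = bp.cross_class_filter(
                up_net, down_net, multiplier=config.bipartite_multiplier
            )
            selected_targets = {"up": up_spec, "down": down_spec}
            for net in (up_net, down_net):
                hio.write_table(bp.degree_table(net), outdir / f"bipartite_{net.label}_degrees.tsv", index=False)
                hio.write_sif(hio.bipartite_to_graph(net), outdir / f"bipartite_{net.label}.sif")
            stage_done(
                "bipartite",
                up_mirnas=len(up_net.mirnas), up_genes=len(up_net.genes), up_edges=len(up_net.edges),
                down_mirnas=len(down_net.mirnas), down_genes=len(down_net.genes),
                down_edges=len(down_net.edges),
                avg_in_up=sel_up.avg_in_degree if sel_up else 0.0,
                avg_in_down=sel_down.avg_in_degree if sel_down else 0.0,
                up_specific_targets=len(up_spec), down_specific_targets=len(down_spec),
            )

    # -- PPI networks + topology + hubs --------------------------------------
    seeds = {"deg": set(deg_network.index)}
    if selected_targets["up"]:
        seeds["up_targets"] = selected_targets["up"]
    if selected_targets["down"]:
        seeds["down_targets"] = selected_targets["down"]

    hub_tables = {}
    for name, seed_set in seeds.items():
        if not seed_set:
            manifest["skipped"].append(f"ppi_{name}: empty seed set")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ppim.EmptyNetworkWarning)
            graph = ppim.build_ppi(
                seed_set, ppi_edges,
                exp_min=config.ppi_exp_min, db_min=config.ppi_db_min,
                string_scale=config.string_scale,
            )
        if graph.graph.number_of_edges() == 0:
            manifest["skipped"].append(f"ppi_{name}: no edge survived the filter")
            continue
        summary = ppim.network_summary(graph)
        hio.write_json(summary, outdir / f"ppi_{name}_summary.json")
        hio.write_sif(graph.graph, outdir / f"ppi_{name}.sif")
        hio.write_graphml(graph.graph, outdir / f"ppi_{name}.graphml")

        result = ct.centrality_table(graph.graph)
        hio.write_table(result.table, outdir / f"centrality_{name}.tsv")
        hio.write_table(
            result.edge_betweenness.rename_axis(["gene_a", "gene_b"]).reset_index(),
            outdir / f"edge_betweenness_{name}.tsv", index=False,
        )
        hubs = nm.select_hubs(result)
        hub_tables[name] = hubs
        hio.write_table(hubs.table(result.table), outdir / f"hubs_{name}.tsv")

        null_info = {}
        if graph.graph.number_of_edges() >= 2:
            nulls = nm.null_test(graph.graph, config.nulls)
            hio.write_table(nulls.long_format(), outdir / f"null_betweenness_{name}.tsv", index=False)
            null_info = {"null_p": nulls.p, "null_z": nulls.z, "reference_avg_betweenness": nulls.reference}
        stage_done(
            f"network_{name}",
            nodes=summary["nodes"], edges=summary["edges"],
            diameter=summary["diameter"], average_distance=summary["average_distance"],
            n_hubs=len(hubs.hubs), isolated_seed_genes=len(graph.isolated), **null_info,
        )

    # -- integration ---------------------------------------------------------
    if up_net is not None and not deg_list.empty:
        directions = deg_list["direction"]
        for direction in ("up", "down"):
            if not (directions == direction).any():
                manifest["skipped"].append(f"integration_{direction}: no DEGs in class")
                continue
            res = integ.ks_target_contrast(directions, up_net, down_net, direction=direction)
            hio.write_table(res.counts, outdir / f"target_counts_{direction}_degs.tsv")
            stage_done(f"integration_{direction}", ks_statistic=res.ks_statistic, ks_p=res.ks_p,
                       n_genes=len(res.counts))
    else:
        manifest["skipped"].append("integration: missing DEGs or bipartite networks")

    if config.gene_sets:
        sets = hio.read_gmt(config.gene_sets)
        universe = set(gene_table.index)
        query = set(deg_list.index) & universe
        if query and sets:
            enr = integ.hypergeom_enrich(query, sets, universe)
            hio.write_table(enr, outdir / "enrichment.tsv")
            stage_done("enrichment", n_sets=len(enr),
                       n_significant=int((enr["q"] <= 0.05).sum()))
        else:
            manifest["skipped"].append("enrichment: empty query or gene-set collection")

    # -- survival -------------------------------------------------------------
    has_surv = mirna_cm.samples["time"].notna() & mirna_cm.samples["event"].notna()
    if not has_surv.any():
        manifest["skipped"].append("survival: no samples with survival data")
    elif de_mirnas.empty:
        manifest["skipped"].append("survival: no DE miRNAs to stratify by")
    else:
        rows = []
        for mirna in de_mirnas.index:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sv.DegenerateStratificationWarning)
                res = sv.test_mirna_survival(
                    mirna, mirna_cm, mirna_norm, rule=config.survival_rule, seed=config.seed
                )
            if res is None:
                continue
            rows.append(
                {"mirna": mirna, "rule": res.rule, "chi_square": res.chi_square,
                 "p": res.p, "excluded": res.excluded,
                 **{f"n_{k}": v for k, v in res.group_sizes.items()}}
            )
        surv_table = pd.DataFrame(rows)
        if len(surv_table):
            surv_table = surv_table.sort_values("p", kind="stable").set_index("mirna")
        hio.write_table(surv_table, outdir / "survival_mirnas.tsv")
        n_sig = int((surv_table["p"] <= 0.05).sum()) if len(surv_table) else 0
        stage_done("survival", n_tested=len(surv_table), n_significant_005=n_sig)

    # -- recovery scoring (synthetic runs only) -------------------------------
    if truth is not None:
        manifest["recovery"] = score_recovery(
            truth, deg_list, de_mirnas, hub_tables, manifest
        )

    manifest["elapsed_s"] = round(_time.time() - t0, 3)
    hio.write_json(manifest, outdir / "manifest.json")
    return manifest


def score_recovery(truth, deg_list, de_mirnas, hub_tables, manifest) -> dict:
    """Precision/recall of each selection stage against the planted truth."""
    out = {}

    def pr(selected: set, positives: set) -> dict:
        tp = len(selected & positives)
        return {
            "n_selected": len(selected),
            "n_true": len(positives),
            "precision": tp / len(selected) if selected else float("nan"),
            "recall": tp / len(positives) if positives else float("nan"),
        }

    out["deg"] = pr(set(deg_list.index), set(truth.de_genes))
    out["de_mirnas"] = pr(set(de_mirnas.index), set(truth.de_mirnas))
    if "deg" in hub_tables and truth.planted_hubs:
        out["hubs"] = pr(set(hub_tables["deg"].hubs), set(truth.planted_hubs))
    return out
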