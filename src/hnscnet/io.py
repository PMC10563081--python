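"""Readers and writers for the tabular and graph formats the pipeline uses.

Tables are TSV; graphs export to SIF and GraphML; gene sets load from GMT;
summaries and manifests are JSON. Everything round-trips losslessly enough
to regenerate a run from its written artifacts.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import CountMatrix, TruthTables


# -- counts + metadata ------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    meta = cm.samples.reset_index()
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    if "stage" in meta.columns:
        meta["stage"] = meta["stage"].astype(object).where(meta["stage"].notna(), pd.NA)
    for col in ("time", "event"):
        if col not in meta.columns:
            meta[col] = np.nan
    return CountMatrix(counts=counts, samples=meta.loc[counts.columns]).validate()


# -- simple tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_target_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mirna_id", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"target map lacks columns {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def read_ppi_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_a", "gene_b", "experimental_score", "database_score"} - set(df.columns)
    if missing:
        raise ValueError(f"PPI edge table lacks columns {sorted(missing)}")
    return df


def write_truth(truth: TruthTables, path) -> None:
    rows = (
        [{"id": f, "kind": "gene", "what": "de", "value": v} for f, v in sorted(truth.de_genes.items())]
        + [{"id": f, "kind": "mirna", "what": "de", "value": v} for f, v in sorted(truth.de_mirnas.items())]
        + [
            {"id": f, "kind": "mirna", "what": "prognostic", "value": v}
            for f, v in sorted(truth.prognostic_mirnas.items())
        ]
        + [{"id": f, "kind": "gene", "what": "planted_hub", "value": 1} for f in sorted(truth.planted_hubs)]
    )
    pd.DataFrame(rows, columns=["id", "kind", "what", "value"]).to_csv(path, sep="\t", index=False)


# -- gene sets (GMT) --------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT: one set per line, tab-separated: name, description, members..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(filter(None, parts[2:]))
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = [
        "\t".join([name, ""] + sorted(members)) for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- graphs -----------------------------------------------------------------

def write_sif(g: nx.Graph, path, interaction: str = "pp") -> None:
    lines = [f"{u}\t{interaction}\t{v}" for u, v in sorted(map(tuple, map(sorted, g.edges)))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def bipartite_to_graph(net) -> nx.Graph:
    """Bipartite net as an nx graph with 'side' and 'class' node attributes
    (for SIF/GraphML export)."""
    g = nx.Graph()
    for m in net.mirnas:
        g.add_node(m, side="mirna", klass=net.label)
    for gene in net.genes:
        g.add_node(gene, side="gene", klass=net.label)
    g.add_edges_from(net.edges)
    return g


# -- json -------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
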