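"""Protein-protein interaction graph assembly and summary statistics.

Edges come from a table with per-channel evidence scores ("experimental"
and "database", each in [0, 1]); an edge is retained iff both endpoints
are in the seed gene set and at least one channel clears its threshold
(strict greater-than). Path statistics are computed on the largest
connected component.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class EmptyNetworkWarning(UserWarning):
    pass


@dataclass
class PPIGraph:
    graph: nx.Graph
    isolated: set = field(default_factory=set)  # seed genes with no surviving edge

    @property
    def largest_component(self) -> nx.Graph:
        if self.graph.number_of_nodes() == 0:
            return self.graph
        nodes = max(nx.connected_components(self.graph), key=lambda c: (len(c), sorted(c)))
        return self.graph.subgraph(nodes)


def build_ppi(
    seed_genes,
    edge_table: pd.DataFrame,
    exp_min: float = 0.1,
    db_min: float = 0.3,
    string_scale: bool = False,
) -> PPIGraph:
    """Filter an edge table down to an undirected evidence-backed graph.

    Keeps an edge iff both endpoints are seed genes AND
    (experimental > exp_min OR database > db_min). Self-loops are dropped;
    duplicate undirected edges are collapsed keeping the per-channel
    maximum score. ``string_scale=True`` divides scores by 1000 first
    (guard for the 0-1000 integer score dialect). Scores outside [0, 1]
    after scaling are a hard error.
    """
    seed = set(seed_genes)
    if not seed:
        raise ValueError("seed gene set is empty")
    t = edge_table.copy()
    for col in ("gene_a", "gene_b", "experimental_score", "database_score"):
        if col not in t.columns:
            raise ValueError(f"edge table lacks column {col!r}")
    if string_scale:
        t["experimental_score"] = t["experimental_score"] / 1000.0
        t["database_score"] = t["database_score"] / 1000.0
    scores = t[["experimental_score", "database_score"]].to_numpy(dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError(
            "evidence scores outside [0, 1]; if these are 0-1000 integer "
            "scores, pass string_scale=True"
        )

    keep = (
        t["gene_a"].isin(seed)
        & t["gene_b"].isin(seed)
        & (t["gene_a"] != t["gene_b"])
        & ((t["experimental_score"] > exp_min) | (t["database_score"] > db_min))
    )
    g = nx.Graph()
    for a, b, e, d in t.loc[
        keep, ["gene_a", "gene_b", "experimental_score", "database_score"]
    ].itertuples(index=False):
        u, v = sorted((a, b))
        if g.has_edge(u, v):
            g[u][v]["experimental_score"] = max(g[u][v]["experimental_score"], e)
            g[u][v]["database_score"] = max(g[u][v]["database_score"], d)
        else:
            g.add_edge(u, v, experimental_score=float(e), database_score=float(d))
    isolated = seed - set(g.nodes)
    if g.number_of_edges() == 0:
        warnings.warn("no edge survived the evidence filter", EmptyNetworkWarning)
    return PPIGraph(graph=g, isolated=isolated)


def all_pairs_distances(g: nx.Graph) -> tuple[list, np.ndarray]:
    """BFS all-pairs distance matrix over sorted nodes; -1 = unreachable."""
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), -1, dtype=np.int32)
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    wi = index[w]
                    if dist[si, wi] < 0:
                        dist[si, wi] = d
                        nxt.append(w)
            frontier = nxt
    return nodes, dist


def network_summary(ppi: PPIGraph | nx.Graph) -> dict:
    """Node/edge counts plus diameter and average distance of the largest
    connected component (mean shortest-path length over connected pairs)."""
    g = ppi.graph if isinstance(ppi, PPIGraph) else ppi
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = sorted(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    lcc = g.subgraph(comps[-1])
    _, dist = all_pairs_distances(lcc)
    n = dist.shape[0]
    if n > 1:
        off = dist[~np.eye(n, dtype=bool)]
        diameter = int(off.max())
        average_distance = float(off.mean())
    else:
        diameter = 0
        average_distance = 0.0
    return {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "n_components": len(comps),
        "component_sizes": sorted((len(c) for c in comps), reverse=True),
        "lcc_nodes": lcc.number_of_nodes(),
        "lcc_edges": lcc.number_of_edges(),
        "diameter": diameter,
        "average_distance": average_distance,
    }
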