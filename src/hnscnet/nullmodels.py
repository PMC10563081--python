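"""Composite hub selection and degree-preserving null models.

Hubs are nodes whose betweenness, centroid and bridging centralities are
all strictly above the corresponding network-wide averages. Whether the
reference network's topology is unusual is assessed against randomized
networks generated by double-edge-swap rewiring, which preserves every
node's degree exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .centrality import CentralityResult
from .config import NullModelConfig

HUB_CENTRALITIES = ("betweenness", "centroid", "bridging")


@dataclass
class HubSelection:
    flags: pd.DataFrame  # per-node above-average flags + "hub" column
    hubs: list  # hub nodes ranked by betweenness desc, ties by node id
    averages: pd.Series  # the three component-wide means used as thresholds

    def table(self, centralities: pd.DataFrame) -> pd.DataFrame:
        """Export-ready hub table: centralities, flags, hub flag, rank."""
        out = centralities[list(HUB_CENTRALITIES)].join(
            self.flags, lsuffix="", rsuffix="_above_avg"
        )
        rank = pd.Series(
            {node: i + 1 for i, node in enumerate(self.hubs)}, dtype="Int64"
        )
        out["rank"] = rank.reindex(out.index)
        return out


def select_hubs(result: CentralityResult) -> HubSelection:
    """Composite rule: strictly above the component mean on all of
    betweenness, centroid and bridging."""
    table = result.table
    averages = table[list(HUB_CENTRALITIES)].mean(axis=0)
    flags = pd.DataFrame(
        {c: table[c] > averages[c] for c in HUB_CENTRALITIES}, index=table.index
    )
    flags["hub"] = flags.all(axis=1)
    hub_nodes = table.index[flags["hub"]]
    hubs = sorted(hub_nodes, key=lambda v: (-table.loc[v, "betweenness"], str(v)))
    return HubSelection(flags=flags, hubs=hubs, averages=averages)


@dataclass
class RandomizationResult:
    graphs: list  # of nx.Graph
    flagged: list  # replicate index equals original (no legal swap found)
    swap_counts: list
    edge_jaccard: list  # overlap with the original edge set (mixing diagnostic)


def _double_edge_swap(edges: list, rng: np.random.Generator, n_swaps: int, max_tries: int):
    """In-place double-edge swaps on a canonical (u<v) edge list.

    Picks two edges (a,b), (c,d) and rewires to (a,d), (c,b); a swap is
    rejected if it would create a self-loop or a duplicate edge. Degrees
    are invariant. Returns the number of successful swaps."""
    m = len(edges)
    edge_set = set(edges)
    successes = 0
    tries = 0
    while successes < n_swaps and tries < max_tries:
        batch = min(4096, max_tries - tries)
        idx = rng.integers(0, m, size=(batch, 2))
        flips = rng.integers(0, 2, size=batch)
        for (i, j), flip in zip(idx, flips):
            tries += 1
            if successes >= n_swaps:
                break
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if flip:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            e1 = (a, d) if a < d else (d, a)
            e2 = (c, b) if c < b else (b, c)
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set.remove(edges[i])
            edge_set.remove(edges[j])
            edge_set.add(e1)
            edge_set.add(e2)
            edges[i] = e1
            edges[j] = e2
            successes += 1
    return successes


def randomize(g: nx.Graph, config: NullModelConfig) -> RandomizationResult:
    """Degree-preserving randomized replicates of ``g``.

    Each replicate applies ``swaps_per_edge * |E|`` successful double-edge
    swaps (independent seeded streams per replicate). Graphs with no legal
    swap (e.g. stars) come back identical to the input and are flagged.
    """
    config.validate()
    if g.number_of_edges() < 2:
        raise ValueError("randomization needs at least 2 edges")
    base_edges = sorted(tuple(sorted(e)) for e in g.edges)
    orig_set = set(base_edges)
    m = len(base_edges)
    target = config.swaps_per_edge * m
    children = np.random.SeedSequence(entropy=int(config.seed)).spawn(config.n_random)

    graphs, flagged, swap_counts, jaccard = [], [], [], []
    for ss in children:
        rng = np.random.default_rng(ss)
        edges = list(base_edges)
        done = _double_edge_swap(edges, rng, target, max_tries=20 * target + 100)
        rg = nx.Graph()
        rg.add_nodes_from(g.nodes)
        rg.add_edges_from(edges)
        graphs.append(rg)
        swap_counts.append(done)
        flagged.append(done == 0)
        inter = len(orig_set & set(edges))
        jaccard.append(inter / (2 * m - inter))
    return RandomizationResult(graphs, flagged, swap_counts, jaccard)


def average_betweenness(g: nx.Graph) -> float:
    """Mean node betweenness (unordered pairs, raw values) on the largest
    connected component, computed at C speed via igraph."""
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(comp)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.subgraph(nodes).edges]
    graph = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return float(np.mean(graph.betweenness()))


@dataclass
class NullResult:
    null: np.ndarray  # statistic per replicate
    reference: float
    p: float  # two-sided empirical p with add-one correction
    z: float
    flagged_fraction: float
    statistic_name: str = "average_betweenness"

    def long_format(self) -> pd.DataFrame:
        """Violin-plot-ready frame: one row per value, labelled source."""
        rows = pd.DataFrame(
            {"source": "random", "value": self.null, "statistic": self.statistic_name}
        )
        ref = pd.DataFrame(
            {"source": ["reference"], "value": [self.reference], "statistic": [self.statistic_name]}
        )
        return pd.concat([rows, ref], ignore_index=True)


def null_test(g: nx.Graph, config: NullModelConfig, statistic=average_betweenness) -> NullResult:
    """Compare a network statistic against its degree-preserving null.

    The statistic (default: average betweenness of the largest component)
    is computed on the reference graph and on every randomized replicate;
    the two-sided empirical p is
    (1 + #{|null_i - mean| >= |ref - mean|}) / (n_random + 1).
    """
    rand = randomize(g, config)
    flagged_fraction = float(np.mean(rand.flagged))
    if flagged_fraction > 0.1:
        raise ValueError(
            f"randomization failed for {flagged_fraction:.0%} of replicates; "
            "graph admits too few legal swaps"
        )
    null = np.array([statistic(rg) for rg in rand.graphs])
    reference = float(statistic(g))
    center = null.mean()
    extreme = np.abs(null - center) >= abs(reference - center)
    p = (1 + int(extreme.sum())) / (len(null) + 1)
    sd = null.std(ddof=1) if len(null) > 1 else 0.0
    z = (reference - center) / sd if sd > 0 else 0.0
    return NullResult(
        null=null,
        reference=reference,
        p=float(p),
        z=float(z),
        flagged_fraction=flagged_fraction,
    )
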