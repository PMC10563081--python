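"""Node and edge centrality suite for undirected, unweighted graphs.

Implements the nine node centralities (degree, betweenness, stress,
closeness, eccentricity, radiality, centroid, eigenvector, bridging) plus
edge betweenness and the network-level diameter / average distance, with
the conventions used by topology tools for protein networks:

- betweenness / stress / edge betweenness over unordered node pairs;
- closeness(v) = 1 / sum_w d(v, w) and eccentricity(v) = 1 / max_w d(v, w)
  (reciprocal forms, so both lie in (0, 1] on a connected graph);
- radiality(v) = sum_{w != v} (diameter + 1 - d(v, w)) / (n - 1);
- centroid(v) = min over opponents w of [#nodes strictly closer to v] -
  [#nodes strictly closer to w], endpoints and ties counting for neither;
- bridging(v) = betweenness(v) * bridging_coefficient(v), with
  BC(v) = (1/deg v) / sum_{u in N(v)} 1/deg(u);
- eigenvector: principal (Perron) eigenvector of the adjacency matrix,
  nonnegative, unit Euclidean norm.

All quantities are computed on the largest connected component, with
deterministic sorted-node iteration order. Betweenness values are raw
(unnormalized). Everything is exact — no sampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CentralityResult:
    nodes: list  # sorted nodes of the largest connected component
    table: pd.DataFrame  # per-node centralities, indexed by node
    edge_betweenness: pd.Series  # indexed by (u, v) tuples, u < v
    diameter: int
    average_distance: float

    @property
    def averages(self) -> pd.Series:
        return self.table.mean(axis=0)


def _largest_component(g: nx.Graph) -> list:
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    return sorted(comp)


def _brandes(adj: list[list[int]], n: int):
    """Single pass over all sources: Brandes' dependency accumulation.

    Returns (betweenness, stress, edge_betweenness dict, distance matrix),
    all for unordered pairs (raw sums halved once at the end).
    """
    bet = np.zeros(n)
    stress = np.zeros(n)
    ebc: dict[tuple[int, int], float] = {}
    dist = np.full((n, n), -1, dtype=np.int32)

    for s in range(n):
        sigma = np.zeros(n)
        d = dist[s]
        d[s] = 0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = [s]
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if d[w] < 0:
                        d[w] = d[u] + 1
                        nxt.append(w)
                        order.append(w)
                    if d[w] == d[u] + 1:
                        sigma[w] += sigma[u]
                        preds[w].append(u)
            frontier = nxt
        delta = np.zeros(n)
        cont = np.zeros(n)  # geodesic continuations for stress
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                c = sigma[v] * coeff
                delta[v] += c
                key = (v, w) if v < w else (w, v)
                ebc[key] = ebc.get(key, 0.0) + c
                cont[v] += 1.0 + cont[w]
            if w != s:
                bet[w] += delta[w]
                stress[w] += sigma[w] * cont[w]
    bet /= 2.0
    stress /= 2.0
    for k in ebc:
        ebc[k] /= 2.0
    return bet, stress, ebc, dist


def _centroid(dist: np.ndarray) -> np.ndarray:
    """centroid(v) = min_{w != v} f(v, w), f(v, w) = gamma_v(w) - gamma_w(v)
    with gamma_v(w) = #{u not in {v, w} : d(u, v) < d(u, w)}.

    The u = v and u = w boundary terms cancel in the difference, so
    f(v, w) = #[column v < column w] - #[column v > column w] elementwise
    over all rows u."""
    n = dist.shape[0]
    cent = np.zeros(n, dtype=np.int64)
    if n == 1:
        return cent
    for v in range(n):
        col = dist[:, v : v + 1]
        less = (col < dist).sum(axis=0)
        greater = (col > dist).sum(axis=0)
        f = less - greater
        f[v] = np.iinfo(np.int64).max  # exclude w = v from the min
        cent[v] = f.min()
    return cent


def eigenvector_centrality(g_or_adj, tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Principal eigenvector of the adjacency matrix by power iteration.

    Iterates on A + I (same eigenvectors, strictly dominant top eigenvalue
    even on bipartite graphs) from a uniform positive start; converges to
    the nonnegative Perron vector, returned with unit Euclidean norm.
    """
    if isinstance(g_or_adj, nx.Graph):
        nodes = sorted(g_or_adj.nodes)
        a = nx.to_scipy_sparse_array(g_or_adj, nodelist=nodes, format="csr", dtype=float)
    else:
        a = sparse.csr_array(g_or_adj, dtype=float)
    n = a.shape[0]
    if n == 1:
        return np.ones(1)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v + v
        norm = np.linalg.norm(w)
        if norm == 0:
            return v
        w /= norm
        if np.linalg.norm(w - v) <= tol * np.linalg.norm(w):
            return np.abs(w)
        v = w
    return np.abs(v)


def centrality_table(g: nx.Graph) -> CentralityResult:
    """Compute the full suite on the largest connected component of ``g``."""
    nodes = _largest_component(g)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [sorted(index[w] for w in g.neighbors(v)) for v in nodes]
    degree = np.array([len(a) for a in adj], dtype=float)

    bet, stress, ebc_idx, dist = _brandes(adj, n)

    if n > 1:
        mask = ~np.eye(n, dtype=bool)
        dsum = np.where(mask, dist, 0).sum(axis=1).astype(float)
        dmax = np.where(mask, dist, 0).max(axis=1).astype(float)
        diameter = int(dist[mask].max())
        average_distance = float(dist[mask].mean())
        closeness = 1.0 / dsum
        eccentricity = 1.0 / dmax
        radiality = (diameter + 1.0 - dsum / (n - 1))
        # sum_{w != v}(diam + 1 - d) / (n-1) = diam + 1 - dsum/(n-1)
    else:
        diameter = 0
        average_distance = 0.0
        closeness = np.array([1.0])
        eccentricity = np.array([1.0])
        radiality = np.array([0.0])

    centroid = _centroid(dist).astype(float)
    eig = eigenvector_centrality(g.subgraph(nodes)) if n > 1 else np.ones(1)

    inv_deg = 1.0 / degree
    nbr_invdeg = np.array([sum(inv_deg[w] for w in adj[v]) for v in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        bridging_coeff = np.where(nbr_invdeg > 0, inv_deg / nbr_invdeg, 0.0)
    bridging = bet * bridging_coeff

    table = pd.DataFrame(
        {
            "degree": degree,
            "betweenness": bet,
            "stress": stress,
            "closeness": closeness,
            "eccentricity": eccentricity,
            "radiality": radiality,
            "centroid": centroid,
            "eigenvector": eig,
            "bridging": bridging,
        },
        index=pd.Index(nodes, name="node"),
    )
    ebc = pd.Series(
        {(nodes[i], nodes[j]): v for (i, j), v in sorted(ebc_idx.items())},
        name="edge_betweenness",
        dtype=float,
    )
    return CentralityResult(
        nodes=nodes,
        table=table,
        edge_betweenness=ebc,
        diameter=diameter,
        average_distance=average_distance,
    )


# -- thin single-centrality wrappers (convenience) -------------------------

def betweenness(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["betweenness"]


def stress(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["stress"]


def edge_betweenness(g: nx.Graph) -> pd.Series:
    return centrality_table(g).edge_betweenness


def closeness(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["closeness"]


def eccentricity(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["eccentricity"]


def radiality(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["radiality"]


def centroid(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["centroid"]


def bridging(g: nx.Graph) -> pd.Series:
    return centrality_table(g).table["bridging"]


def shortest_path_stats(g: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """All-pairs distances d(v, w) and geodesic counts sigma_vw on the
    largest connected component (sorted nodes)."""
    nodes = _largest_component(g)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [sorted(index[w] for w in g.neighbors(v)) for v in nodes]
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in range(n):
        d = dist[s]
        sg = sigma[s]
        d[s] = 0
        sg[s] = 1.0
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if d[w] < 0:
                        d[w] = d[u] + 1
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sg[w] += sg[u]
            frontier = nxt
    return nodes, dist, sigma
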