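"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — exhaustive geodesic enumeration,
cubic loops, dense linear algebra — and shares no code with the package,
so agreement is a real cross-check.
"""
from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def random_connected_graph(rng: np.random.Generator, n_max: int = 25) -> nx.Graph:
    """A random connected simple graph with 3..n_max nodes."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.1, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= 2:
            return g


def all_geodesics(g: nx.Graph) -> dict:
    """{(s, t): list of all shortest paths (as node tuples)} for s < t."""
    paths = {}
    nodes = sorted(g.nodes)
    for s, t in combinations(nodes, 2):
        paths[(s, t)] = [tuple(p) for p in nx.all_shortest_paths(g, s, t)]
    return paths


def brute_betweenness_stress_edge(g: nx.Graph):
    """Betweenness, stress and edge betweenness by enumerating every
    geodesic of every unordered pair."""
    bet = {v: 0.0 for v in g.nodes}
    stress = {v: 0.0 for v in g.nodes}
    ebc = {tuple(sorted(e)): 0.0 for e in g.edges}
    for (s, t), paths in all_geodesics(g).items():
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / sigma
                stress[v] += 1.0
            for u, w in zip(path, path[1:]):
                ebc[tuple(sorted((u, w)))] += 1.0 / sigma
    return bet, stress, ebc


def brute_distance_metrics(g: nx.Graph):
    """Closeness (reciprocal sum), eccentricity (reciprocal max), radiality,
    diameter and average distance from explicit BFS distances."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    diameter = max(dist[u][v] for u in nodes for v in nodes)
    total = sum(dist[u][v] for u in nodes for v in nodes if u != v)
    avg_dist = total / (n * (n - 1))
    closeness = {v: 1.0 / sum(dist[v][w] for w in nodes if w != v) for v in nodes}
    eccentricity = {v: 1.0 / max(dist[v][w] for w in nodes if w != v) for v in nodes}
    radiality = {
        v: sum(diameter + 1 - dist[v][w] for w in nodes if w != v) / (n - 1)
        for v in nodes
    }
    return closeness, eccentricity, radiality, diameter, avg_dist


def brute_centroid(g: nx.Graph) -> dict:
    """Cubic triple loop over (v, w, u) with explicit tie/endpoint rules."""
    nodes = sorted(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    out = {}
    for v in nodes:
        best = None
        for w in nodes:
            if w == v:
                continue
            gamma_v = sum(
                1 for u in nodes if u not in (v, w) and dist[u][v] < dist[u][w]
            )
            gamma_w = sum(
                1 for u in nodes if u not in (v, w) and dist[u][w] < dist[u][v]
            )
            f = gamma_v - gamma_w
            best = f if best is None else min(best, f)
        out[v] = float(best)
    return out


def brute_eigenvector(g: nx.Graph) -> np.ndarray:
    """Principal eigenvector via dense symmetric eigendecomposition."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def brute_bridging(g: nx.Graph) -> dict:
    bet, _, _ = brute_betweenness_stress_edge(g)
    out = {}
    for v in g.nodes:
        deg = g.degree(v)
        denom = sum(1.0 / g.degree(u) for u in g.neighbors(v))
        out[v] = bet[v] * (1.0 / deg) / denom
    return out


def bh_adjust_brute(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written independently: sort, scale by
    m/rank, enforce monotonicity from the largest rank down, clip at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.clip(adj, 0.0, 1.0)


def brute_ks_statistic(x, y) -> float:
    """sup |ECDF_x - ECDF_y| over every observed point, double loop."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def brute_logrank(times_a, events_a, times_b, events_b) -> float:
    """Log-rank chi-square from an explicit O/E/V table per event time."""
    times_a, events_a = np.asarray(times_a, float), np.asarray(events_a, int)
    times_b, events_b = np.asarray(times_b, float), np.asarray(events_b, int)
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    group_a = np.concatenate([np.ones(len(times_a)), np.zeros(len(times_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_times[all_events == 1])):
        at_risk = all_times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group_a == 1)).sum()
        d = ((all_times == t) & (all_events == 1)).sum()
        d_a = ((all_times == t) & (all_events == 1) & (group_a == 1)).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var) if var > 0 else 0.0


def hypergeom_tail_brute(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) by explicit summation of hypergeometric pmf terms."""
    from math import comb

    total = comb(big_n, n)
    return sum(
        comb(big_k, i) * comb(big_n - big_k, n - i)
        for i in range(k, min(big_k, n) + 1)
    ) / total
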