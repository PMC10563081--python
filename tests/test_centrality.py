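"""Centrality suite: closed forms, hand values, brute-force and library
cross-checks, and invariance properties."""
import igraph as ig
import networkx as nx
import numpy as np
import pytest

from hnscnet.centrality import centrality_table, eigenvector_centrality, shortest_path_stats
from oracles import (
    brute_betweenness_stress_edge,
    brute_centroid,
    brute_distance_metrics,
    brute_eigenvector,
    random_connected_graph,
)


def test_star_closed_forms():
    for n in range(4, 8):
        res = centrality_table(nx.star_graph(n - 1))  # n nodes total
        t = res.table
        assert t.loc[0, "betweenness"] == pytest.approx((n - 1) * (n - 2) / 2)
        assert t.loc[0, "closeness"] == pytest.approx(1 / (n - 1))
        assert t.loc[0, "eccentricity"] == 1.0
        leaf = t.loc[1]
        assert leaf["betweenness"] == 0.0
        assert leaf["closeness"] == pytest.approx(1 / (2 * (n - 2) + 1))
        assert leaf["eccentricity"] == 0.5


def test_s4_hand_values():
    res = centrality_table(nx.star_graph(3))
    t = res.table
    assert t.loc[0, "centroid"] == 2 and (t.loc[1:, "centroid"] == -2).all()
    # center/leaf eigenvector ratio sqrt(3)
    assert t.loc[0, "eigenvector"] / t.loc[1, "eigenvector"] == pytest.approx(np.sqrt(3))
    # bridging: center betweenness 3 * BC (1/3)/3 = 1/3; leaves 0
    assert t.loc[0, "bridging"] == pytest.approx(1 / 3)
    assert (t.loc[1:, "bridging"] == 0).all()


def test_p4_and_p3_hand_values():
    res = centrality_table(nx.path_graph(4))
    t = res.table
    assert t.loc[1, "betweenness"] == 2.0 and t.loc[2, "betweenness"] == 2.0
    res3 = centrality_table(nx.path_graph(3))
    # middle node: BC = (1/2)/(1+1) = 0.25, betweenness 1 -> bridging 0.25
    assert res3.table.loc[1, "bridging"] == pytest.approx(0.25)


def test_complete_graph_symmetry():
    n = 6
    res = centrality_table(nx.complete_graph(n))
    t = res.table
    assert np.allclose(t["closeness"], 1 / (n - 1))
    assert np.allclose(t["eccentricity"], 1.0)
    assert np.allclose(t["radiality"], 1.0)
    assert np.allclose(t["eigenvector"], 1 / np.sqrt(n))
    assert np.allclose(t["betweenness"], 0.0)
    assert t["centroid"].nunique() == 1  # vertex-transitive


def test_cycle_sigma_counts():
    _, dist, sigma = shortest_path_stats(nx.cycle_graph(4))
    assert dist[0, 2] == 2 and sigma[0, 2] == 2  # two geodesics between opposites
    assert sigma[0, 1] == 1


def test_stress_equals_betweenness_on_trees(rng):
    for _ in range(5):
        g = nx.random_labeled_tree(12, seed=int(rng.integers(2**31)))
        t = centrality_table(g).table
        assert np.allclose(t["stress"], t["betweenness"])


def test_radiality_identity_mean_radiality():
    """node-averaged radiality = diameter + 1 - average distance."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = random_connected_graph(rng, n_max=20)
        res = centrality_table(g)
        assert res.table["radiality"].mean() == pytest.approx(
            res.diameter + 1 - res.average_distance, abs=1e-9
        )


def test_matches_brute_force_oracles(rng):
    for _ in range(25):
        g = random_connected_graph(rng, n_max=18)
        res = centrality_table(g)
        t = res.table
        bet, stress, ebc = brute_betweenness_stress_edge(g)
        for v in t.index:
            assert t.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert t.loc[v, "stress"] == pytest.approx(stress[v], abs=1e-9)
        for e, val in ebc.items():
            assert res.edge_betweenness[e] == pytest.approx(val, abs=1e-9)
        clo, ecc, rad, diam, avg = brute_distance_metrics(g)
        for v in t.index:
            assert t.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)
            assert t.loc[v, "eccentricity"] == pytest.approx(ecc[v], abs=1e-12)
            assert t.loc[v, "radiality"] == pytest.approx(rad[v], abs=1e-12)
        cen = brute_centroid(g)
        for v in t.index:
            assert t.loc[v, "centroid"] == cen[v]
        eig = brute_eigenvector(g)
        assert np.allclose(t["eigenvector"].to_numpy(), eig, atol=1e-9)


def test_matches_igraph_betweenness(rng):
    """Independent library cross-check at a different scale."""
    g = nx.barabasi_albert_graph(120, 3, seed=5)
    t = centrality_table(g).table
    graph = ig.Graph(n=120, edges=list(g.edges), directed=False)
    assert np.allclose(t["betweenness"].to_numpy(), graph.betweenness(), atol=1e-8)
    assert t["closeness"].to_numpy() == pytest.approx(
        np.array(graph.closeness()) / (120 - 1), abs=1e-12
    )


def test_label_permutation_equivariance(rng):
    g = random_connected_graph(rng, n_max=15)
    perm = {v: f"node_{int(rng.integers(1000))}_{v}" for v in g.nodes}
    h = nx.relabel_nodes(g, perm)
    tg = centrality_table(g).table
    th = centrality_table(h).table
    for v in g.nodes:
        for col in tg.columns:
            assert tg.loc[v, col] == pytest.approx(th.loc[perm[v], col], abs=1e-9)


def test_betweenness_sum_identity(rng):
    """sum_v betweenness(v) = sum_{s<t} (d(s,t) - 1) on connected graphs."""
    for _ in range(5):
        g = random_connected_graph(rng, n_max=20)
        res = centrality_table(g)
        nodes, dist, _ = shortest_path_stats(g)
        n = len(nodes)
        iu = np.triu_indices(n, k=1)
        assert res.table["betweenness"].sum() == pytest.approx(
            float((dist[iu] - 1).sum()), abs=1e-9
        )


def test_computed_on_largest_component():
    g = nx.path_graph(5)
    g.add_edges_from([("a", "b")])
    res = centrality_table(g)
    assert set(res.table.index) == set(range(5))


def test_eigenvector_converges_on_bipartite_graph():
    g = nx.cycle_graph(6)  # bipartite; plain power iteration would oscillate
    v = eigenvector_centrality(g)
    assert np.allclose(v, 1 / np.sqrt(6), atol=1e-9)


def test_adding_edge_never_increases_distances(rng):
    g = random_connected_graph(rng, n_max=15)
    nodes, dist, _ = shortest_path_stats(g)
    non_edges = list(nx.non_edges(g))
    if non_edges:
        g2 = g.copy()
        g2.add_edge(*non_edges[0])
        _, dist2, _ = shortest_path_stats(g2)
        assert (dist2 <= dist).all()
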