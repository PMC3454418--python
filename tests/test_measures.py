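"""Global network measures vs hand values and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

import songnet as sn
from songnet.construction import SongDigraph, SongNetwork
from songnet.measures import UndefinedMeasureError

from conftest import brute_force_C, brute_force_L, random_connected_graph


def undirected(*edges) -> SongNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return SongNetwork(g)


class TestAveragePathLength:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([("a", "b"), ("b", "c"), ("a", "c")], 1.0),          # triangle
            ([("a", "b"), ("b", "c")], 4 / 3),                    # path
            ([("h", "x"), ("h", "y"), ("h", "z")], 1.5),          # star
        ],
    )
    def test_hand_values(self, edges, expected):
        assert sn.average_path_length(undirected(*edges)) == pytest.approx(expected)

    def test_directed_uses_arc_direction(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        # reachable ordered pairs: a->b (1), a->c (2), b->c (1)
        assert sn.average_path_length(SongDigraph(g)) == pytest.approx(4 / 3)

    def test_unreachable_pairs_excluded(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert sn.average_path_length(SongNetwork(g)) == pytest.approx(1.0)

    def test_edgeless_raises(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(UndefinedMeasureError):
            sn.average_path_length(SongNetwork(g))


class TestClustering:
    def test_triangle_is_one(self):
        assert sn.clustering_coefficient(
            undirected(("a", "b"), ("b", "c"), ("a", "c"))
        ) == pytest.approx(1.0)

    def test_path_is_zero(self):
        assert sn.clustering_coefficient(
            undirected(("a", "b"), ("b", "c"))
        ) == pytest.approx(0.0)

    def test_kite_hand_value(self):
        kite = undirected(("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"))
        assert sn.local_clustering(kite, "a") == pytest.approx(1.0)
        assert sn.local_clustering(kite, "c") == pytest.approx(1 / 3)
        assert sn.local_clustering(kite, "d") == pytest.approx(0.0)
        assert sn.clustering_coefficient(kite) == pytest.approx(7 / 12)

    def test_directed_rejected(self):
        with pytest.raises(TypeError):
            sn.clustering_coefficient(SongDigraph(nx.DiGraph([("a", "b")])))


class TestDegreeDistribution:
    def test_triangle(self):
        net = undirected(("a", "b"), ("b", "c"), ("a", "c"))
        assert sn.degree_distribution(net) == {2: 1.0}
        assert sn.average_degree(net) == pytest.approx(2.0)

    def test_star(self):
        net = undirected(("h", "x"), ("h", "y"), ("h", "z"))
        assert sn.degree_distribution(net) == {1: 0.75, 3: 0.25}
        assert sn.average_degree(net) == pytest.approx(1.5)

    def test_digraph_total_degree_default(self):
        d = SongDigraph(nx.DiGraph([("a", "b"), ("b", "a")]))
        assert sn.degree_distribution(d) == {2: 1.0}
        assert sn.degree_distribution(d, kind="in") == {1: 1.0}

    def test_normalization_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = SongNetwork(random_connected_graph(rng))
            assert sum(sn.degree_distribution(net).values()) == pytest.approx(1.0)


class TestSmallWorldnessAndZ:
    def test_observed_row_value(self):
        assert round(sn.small_worldness(0.21, 3.15, 0.03, 2.98), 2) == 6.62

    def test_identity_cases(self):
        assert sn.small_worldness(0.2, 3.0, 0.2, 3.0) == pytest.approx(1.0)
        assert sn.small_worldness(0.2, 4.0, 0.1, 2.0) == pytest.approx(1.0)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            sn.small_worldness(0.0, 3.0, 0.1, 2.0)

    @pytest.mark.parametrize(
        "obs, mean, sd, expected",
        [(0.21, 0.03, 0.01, 18.0), (3.15, 2.98, 0.09, 1.888888888888), (5, 5, 2, 0.0)],
    )
    def test_z_score(self, obs, mean, sd, expected):
        assert sn.z_score(obs, mean, sd) == pytest.approx(expected)

    def test_z_score_sd_zero_rejected(self):
        with pytest.raises(ValueError):
            sn.z_score(1.0, 1.0, 0.0)


def test_complete_graph_invariants():
    for n in (3, 5, 8):
        net = SongNetwork(nx.complete_graph(n))
        assert sn.average_path_length(net) == pytest.approx(1.0)
        assert sn.clustering_coefficient(net) == pytest.approx(1.0)
        assert sn.average_degree(net) == pytest.approx(n - 1)


def test_oracle_battery_L_and_C():
    """L and C agree exactly with plain-BFS / pair-counting brute force."""
    rng = np.random.default_rng(42)
    for _ in range(40):
        g = random_connected_graph(rng)
        net = SongNetwork(g)
        assert sn.average_path_length(net) == pytest.approx(
            brute_force_L(g), abs=1e-12
        )
        assert sn.clustering_coefficient(net) == pytest.approx(
            brute_force_C(g), abs=1e-12
        )


def test_oracle_battery_directed_L():
    rng = np.random.default_rng(43)
    for _ in range(20):
        n = int(rng.integers(3, 10))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)),
                                directed=True)
        if g.number_of_edges() == 0:
            continue
        assert sn.average_path_length(SongDigraph(g)) == pytest.approx(
            brute_force_L(g), abs=1e-12
        )


def test_compute_measures_bundle(walk_corpus):
    _, sun = sn.build_networks(walk_corpus)
    ms = sn.compute_measures(sun)
    assert ms.n == sun.n and ms.m == ms.n
    assert math.isclose(sum(ms.degree_probability.values()), 1.0)
    assert ms.L is not None and ms.L >= 1
    assert 0 <= ms.C <= 1
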