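"""Network construction, clustering statistics and threshold selection."""

import networkx as nx
import numpy as np
import pytest

from gofnet import fixtures as fx
from gofnet import network as net_mod
from gofnet.network import (
    WeightedGeneNetwork,
    build_network,
    clustering_coefficient,
    global_properties,
    random_clustering_expectation,
    select_first_stop,
    threshold_scan,
)
from gofnet.similarity import GeneSimilarity

from conftest import brute_triangle_clustering


def pair(a, b, w):
    return GeneSimilarity(a, b, 0.0, 0.0, 0.0, w)


TOY_TABLE = [
    pair("a", "b", 0.9), pair("a", "c", 0.55), pair("b", "c", 0.5),
    pair("c", "d", 0.3), pair("d", "e", 0.1), pair("a", "e", 0.0),
]


def wrap(graph):
    return WeightedGeneNetwork(graph=nx.Graph(graph))


class TestBuildNetwork:
    def test_threshold_zero_keeps_every_nonzero_pair(self):
        net = build_network(TOY_TABLE, "INT", 0.0)
        assert net.n_edges == 5  # the zero-similarity pair is never an edge
        assert net.nodes == {"a", "b", "c", "d", "e"}

    def test_threshold_above_all_weights_gives_empty_network(self):
        net = build_network(TOY_TABLE, "INT", 1.0)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_direct_inspection_at_half(self):
        net = build_network(TOY_TABLE, "INT", 0.5)
        assert set(map(frozenset, net.graph.edges())) == {
            frozenset({"a", "b"}), frozenset({"a", "c"}), frozenset({"b", "c"})
        }
        assert "d" not in net.nodes  # isolated genes are dropped

    def test_edges_are_nested_across_thresholds(self):
        recs, _ = fx.make_planted_network(fx.FixtureSpec(seed=1, clique_size=8))
        previous = None
        for t in (0.2, 0.5, 0.8, 0.9):
            edges = set(map(frozenset, build_network(recs, "INT", t).graph.edges()))
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestClusteringCoefficient:
    def test_triangle_and_star_closed_forms(self):
        assert clustering_coefficient(wrap(nx.complete_graph(3))) == pytest.approx(1.0)
        assert clustering_coefficient(wrap(nx.star_graph(4))) == 0.0
        assert clustering_coefficient(wrap(nx.Graph())) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_triangle_counting(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            g = nx.gnp_random_graph(int(rng.integers(5, 21)), rng.uniform(0.1, 0.6),
                                    seed=int(rng.integers(2**31)))
            assert clustering_coefficient(wrap(g)) == pytest.approx(
                brute_triangle_clustering(g)
            )


class TestRandomExpectation:
    def test_complete_graph_closed_form(self):
        # N=4, k=3 for all: (9-3)^2 / (4*27) = 1/3
        assert random_clustering_expectation(wrap(nx.complete_graph(4))) == pytest.approx(1 / 3)

    def test_empty_graph_is_zero(self):
        assert random_clustering_expectation(wrap(nx.Graph())) == 0.0

    def test_erdos_renyi_monte_carlo(self):
        """Configuration-model expectation vs sampled ER clustering."""
        n, p = 200, 0.1
        samples = [
            clustering_coefficient(wrap(nx.fast_gnp_random_graph(n, p, seed=s)))
            for s in range(100)
        ]
        expectations = [
            random_clustering_expectation(wrap(nx.fast_gnp_random_graph(n, p, seed=s)))
            for s in range(100)
        ]
        spread = np.std(samples, ddof=1)
        assert abs(np.mean(expectations) - np.mean(samples)) < 3 * spread


class TestSelectFirstStop:
    GRID = [round(i / 100, 2) for i in range(101)]

    def test_monotone_decreasing_stops_at_first_comparison(self):
        delta = list(np.linspace(1.0, 0.0, 101))
        selected, hit_end = select_first_stop(delta, self.GRID)
        assert selected == 0.01 and not hit_end

    def test_strictly_increasing_hits_grid_end_with_flag(self):
        delta = list(np.linspace(0.0, 1.0, 101))
        selected, hit_end = select_first_stop(delta, self.GRID)
        assert selected == 1.00 and hit_end

    def test_interior_peak_is_selected(self):
        delta = [min(i, 80 - i) / 100 for i in range(101)]
        selected, _ = select_first_stop(delta, self.GRID)
        assert selected == 0.40

    def test_plateau_terminates_the_increasing_run(self):
        delta = [min(i, 30) / 100 for i in range(101)]
        selected, _ = select_first_stop(delta, self.GRID)
        assert selected == 0.30


class TestThresholdScan:
    def test_recovers_planted_thresholds(self):
        hits = 0
        for seed in range(3):
            spec = fx.FixtureSpec(seed=seed, planted_threshold=0.6 + 0.1 * seed)
            recs, truth = fx.make_planted_network(spec)
            scan = threshold_scan(recs, "INT")
            hits += abs(scan.selected - truth["threshold"]) <= 0.0101
        assert hits == 3

    def test_c_obs_at_zero_threshold_equals_full_graph_clustering(self):
        recs, _ = fx.make_planted_network(fx.FixtureSpec(seed=2, clique_size=6))
        scan = threshold_scan(recs, "INT")
        full = build_network(recs, "INT", 0.0)
        assert scan.c_obs[0] == pytest.approx(clustering_coefficient(full))
        assert scan.edge_count == sorted(scan.edge_count, reverse=True)
        assert scan.delta == pytest.approx(
            [o - r for o, r in zip(scan.c_obs, scan.c_rand)]
        )

    def test_all_zero_similarities_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            threshold_scan([pair("a", "b", 0.0)], "INT")


class TestGlobalProperties:
    def test_path_graph_closed_forms(self):
        props = global_properties(wrap(nx.path_graph(3)))
        assert props["diameter"] == 2
        assert props["density"] == pytest.approx(2 / 3)
        assert props["connected_components"] == 1

    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        props = global_properties(wrap(g))
        assert props["connected_components"] == 2
        assert props["clustering_coefficient"] == pytest.approx(1.0)

    def test_random_graph_against_independent_formulas(self):
        g = nx.gnp_random_graph(30, 0.15, seed=42)
        props = global_properties(wrap(g))
        # independent oracles: BFS eccentricities and degree formulas
        largest = g.subgraph(max(nx.connected_components(g), key=len))
        dist = dict(nx.all_pairs_shortest_path_length(largest))
        ecc = [max(d.values()) for d in dist.values()]
        assert props["diameter"] == max(ecc)
        assert props["radius"] == min(ecc)
        n_l = largest.number_of_nodes()
        mean_spl = sum(sum(d.values()) for d in dist.values()) / (n_l * (n_l - 1))
        assert props["characteristic_path_length"] == pytest.approx(mean_spl)
        degrees = np.array([d for _, d in g.degree()])
        n = len(degrees)
        assert props["mean_neighbors"] == pytest.approx(degrees.mean())
        assert props["density"] == pytest.approx(
            2 * g.number_of_edges() / (n * (n - 1))
        )
        assert props["centralisation"] == pytest.approx(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
        assert props["heterogeneity"] == pytest.approx(degrees.std() / degrees.mean())
        assert props["clustering_coefficient"] == pytest.approx(
            brute_triangle_clustering(g)
        )


def test_edge_list_round_trip(tmp_path):
    net = build_network(TOY_TABLE, "INT", 0.3)
    path = tmp_path / "edges.tsv"
    net_mod.write_edge_list(net, path)
    again = net_mod.read_edge_list(path)
    assert set(map(frozenset, again.graph.edges())) == set(
        map(frozenset, net.graph.edges())
    )
    for a, b in net.graph.edges():
        assert again.graph[a][b]["weight"] == pytest.approx(net.graph[a][b]["weight"])
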