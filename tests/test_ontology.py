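"""Ontology parsing, descendant counts, T-values and LCA shortest paths."""

import math

import numpy as np
import pytest

from gofnet import ontology as onto
from gofnet.ontology import lca_shortest_path, read_obo, t_values

from conftest import (
    brute_all_up_paths,
    brute_descendant_count,
    ontology_from_parent_map,
    random_parent_dag,
)

MINI_OBO = """format-version: 1.2

[Term]
id: X:0000001
name: root
namespace: biological_process

[Term]
id: X:0000002
name: a
namespace: biological_process
is_a: X:0000001 ! root

[Term]
id: X:0000003
name: b
namespace: biological_process
relationship: part_of X:0000002 ! a
"""


def write(tmp_path, text):
    path = tmp_path / "t.obo"
    path.write_text(text)
    return path


class TestReadObo:
    def test_is_a_and_part_of_both_become_parent_edges(self, tmp_path):
        g = read_obo(write(tmp_path, MINI_OBO))
        assert g.terms == {"X:0000001", "X:0000002", "X:0000003"}
        assert g.graph.number_of_edges() == 2
        assert g.parents("X:0000003") == {"X:0000002"}
        assert g.roots["BP"] == "X:0000001"

    def test_obsolete_terms_are_excluded(self, tmp_path):
        text = MINI_OBO + (
            "\n[Term]\nid: X:0000004\nname: dead\nnamespace: biological_process\n"
            "is_obsolete: true\n"
        )
        g = read_obo(write(tmp_path, text))
        assert "X:0000004" not in g.terms
        assert "X:0000004" in g.obsolete

    def test_has_part_relationship_is_not_a_parent_edge(self, tmp_path):
        text = MINI_OBO + (
            "\n[Term]\nid: X:0000005\nname: c\nnamespace: biological_process\n"
            "is_a: X:0000001 ! root\nrelationship: has_part X:0000002 ! a\n"
        )
        g = read_obo(write(tmp_path, text))
        assert g.parents("X:0000005") == {"X:0000001"}

    def test_multiple_roots_in_one_aspect_is_a_structural_error(self, tmp_path):
        text = MINI_OBO + (
            "\n[Term]\nid: X:0000006\nname: second root\n"
            "namespace: biological_process\n"
        )
        with pytest.raises(onto.StructuralError, match="exactly one root"):
            read_obo(write(tmp_path, text))


class TestDescendantCounts:
    def test_leaf_counts_itself_and_root_counts_all(self, tmp_path):
        g = read_obo(write(tmp_path, MINI_OBO))
        stats = onto.descendant_counts(g)
        assert stats.descendant_count["X:0000003"] == 1
        assert stats.descendant_count["X:0000001"] == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reachability_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            terms, parents = random_parent_dag(rng, int(rng.integers(4, 31)))
            g = ontology_from_parent_map(terms, parents)
            stats = onto.descendant_counts(g)
            for t in terms:
                assert stats.descendant_count[t] == brute_descendant_count(parents, t)


class TestTValues:
    def test_root_is_one_and_single_child_is_half(self):
        g = ontology_from_parent_map(["R", "A"], {"R": set(), "A": {"R"}})
        stats = t_values(g)
        assert stats.t_value["R"] == 1.0
        assert stats.t_value["A"] == pytest.approx(0.5)  # omega = 1/2

    def test_multi_parent_averaging_rule(self):
        # parents with T = 0.5 and 0.3, a common omega of 0.25:
        # T(C) = mean(0.25*0.5, 0.25*0.3) = 0.25 * 0.4 = 0.1
        g = ontology_from_parent_map(
            ["R", "A", "B", "C"],
            {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A", "B"}},
        )
        planted = {("A", "R"): 0.5, ("B", "R"): 0.3, ("C", "A"): 0.25, ("C", "B"): 0.25}
        stats = t_values(g, omega_fn=lambda s, c, p: planted[(c, p)])
        assert stats.t_value["A"] == pytest.approx(0.5)
        assert stats.t_value["B"] == pytest.approx(0.3)
        assert stats.t_value["C"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_values_decrease_below_parent_mean_and_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(100 + seed)
        terms, parents = random_parent_dag(rng, 25)
        g = ontology_from_parent_map(terms, parents)
        stats = t_values(g)
        for t in terms:
            assert 0.0 < stats.t_value[t] <= 1.0
            if parents[t]:
                parent_mean = sum(stats.t_value[p] for p in parents[t]) / len(parents[t])
                assert stats.t_value[t] < parent_mean

    def test_omega_strictly_between_zero_and_one(self):
        rng = np.random.default_rng(7)
        terms, parents = random_parent_dag(rng, 20)
        g = ontology_from_parent_map(terms, parents)
        stats = t_values(g)
        for (child, parent), w in stats.omega.items():
            assert 0.0 < w < 1.0
            assert stats.descendant_count[child] < stats.descendant_count[parent]


class TestLcaShortestPath:
    def test_identical_terms_give_the_degenerate_path(self):
        g = ontology_from_parent_map(["R", "A"], {"R": set(), "A": {"R"}})
        stats = t_values(g)
        assert lca_shortest_path(g, stats, "A", "A") == ["A"]

    def test_siblings_join_through_the_root(self):
        g = ontology_from_parent_map(
            ["R", "A", "B"], {"R": set(), "A": {"R"}, "B": {"R"}}
        )
        stats = t_values(g)
        assert lca_shortest_path(g, stats, "A", "B") == ["A", "R", "B"]

    def test_matches_exhaustive_path_enumeration(self):
        # diamond with two candidate LCAs plus a deeper layer
        parents = {
            "R": set(), "P1": {"R"}, "P2": {"R"}, "M1": {"P1", "P2"},
            "M2": {"P1", "P2"}, "A": {"M1", "M2"}, "B": {"M1"}, "C": {"M2"},
        }
        terms = list(parents)
        g = ontology_from_parent_map(terms, parents)
        stats = t_values(g)
        for t1, t2 in [("A", "B"), ("B", "C"), ("A", "C")]:
            path = lca_shortest_path(g, stats, t1, t2)
            got = (len(path) - 1, sum(stats.t_value[t] for t in path))
            best = min(
                (
                    len(p1) + len(p2) - 2,
                    sum(stats.t_value[t] for t in p1)
                    + sum(stats.t_value[t] for t in p2)
                    - stats.t_value[p1[-1]],
                )
                for p1 in brute_all_up_paths(parents, t1)
                for p2 in brute_all_up_paths(parents, t2)
                if p1[-1] == p2[-1]
            )
            assert got[0] == best[0]
            assert got[1] == pytest.approx(best[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_path_is_symmetric(self, seed):
        rng = np.random.default_rng(200 + seed)
        terms, parents = random_parent_dag(rng, 20)
        g = ontology_from_parent_map(terms, parents)
        stats = t_values(g)
        for _ in range(20):
            t1, t2 = rng.choice(terms, size=2, replace=False)
            forward = lca_shortest_path(g, stats, t1, t2)
            assert forward[::-1] == lca_shortest_path(g, stats, t2, t1)

    def test_cross_aspect_pair_is_a_domain_error(self, toy_ontology):
        g, stats, truth = toy_ontology
        bp = next(t for t, a in truth["aspect"].items() if a == "BP")
        mf = next(t for t, a in truth["aspect"].items() if a == "MF")
        with pytest.raises(ValueError, match="different aspects"):
            lca_shortest_path(g, stats, bp, mf)


def test_generator_truth_agrees_with_pipeline(toy_ontology):
    """The fixture generator's brute-force truth matches the parsed pipeline."""
    g, stats, truth = toy_ontology
    assert g.terms == set(truth["aspect"])
    for term, count in truth["descendant_count"].items():
        assert stats.descendant_count[term] == count
    for term, tv in truth["t_value"].items():
        assert math.isclose(stats.t_value[term], tv, rel_tol=1e-12)
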