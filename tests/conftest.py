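"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gofnet import annotation as ann_mod
from gofnet import fixtures as fx
from gofnet import ontology as onto


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive, independent of the implementation)

def brute_descendant_count(parents: dict[str, set[str]], term: str) -> int:
    """Count terms that reach ``term`` by walking parent links, plus itself."""
    count = 1
    for other in parents:
        if other == term:
            continue
        stack, seen = [other], set()
        while stack:
            node = stack.pop()
            if node == term:
                count += 1
                break
            for p in parents[node]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
    return count


def brute_triangle_clustering(graph) -> float:
    """Mean clustering via O(n^3) triangle counting; 0 for degree < 2."""
    nodes = list(graph.nodes)
    total = 0.0
    for v in nodes:
        nbrs = list(graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if graph.has_edge(nbrs[i], nbrs[j])
        )
        total += 2.0 * links / (k * (k - 1))
    return total / len(nodes) if nodes else 0.0


def brute_all_up_paths(parents: dict[str, set[str]], start: str):
    """Every upward path from ``start`` to every ancestor, by recursion."""
    paths = [[start]]
    frontier = [[start]]
    while frontier:
        nxt = []
        for path in frontier:
            for p in parents[path[-1]]:
                nxt.append(path + [p])
        paths.extend(nxt)
        frontier = nxt
    return paths


# ---------------------------------------------------------------------------
# shared toy pipeline fixtures

@pytest.fixture(scope="session")
def toy_spec() -> fx.FixtureSpec:
    return fx.FixtureSpec(seed=17)


@pytest.fixture(scope="session")
def toy_ontology(tmp_path_factory, toy_spec):
    path = tmp_path_factory.mktemp("onto") / "toy.obo"
    _, truth = fx.make_toy_ontology(toy_spec, path)
    graph = onto.read_obo(path)
    stats = onto.t_values(graph)
    return graph, stats, truth


@pytest.fixture(scope="session")
def toy_annotations(tmp_path_factory, toy_spec, toy_ontology):
    graph, _, onto_truth = toy_ontology
    path = tmp_path_factory.mktemp("ann") / "toy.gaf"
    _, truth = fx.make_annotations(toy_spec, onto_truth, path)
    ann = ann_mod.read_gaf(path, ontology=graph)
    return ann, truth


def random_parent_dag(rng: np.random.Generator, n_terms: int):
    """Random single-rooted parent map over generic term ids."""
    terms = [f"T{i}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        k = 1 if i < 2 or rng.random() < 0.7 else 2
        parents[terms[i]] = {
            terms[int(j)] for j in rng.choice(i, size=min(k, i), replace=False)
        }
    return terms, parents


def ontology_from_parent_map(terms, parents) -> onto.OntologyGraph:
    """Assemble a single-aspect OntologyGraph directly from a parent map."""
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            graph.add_edge(child, p)
    aspect = {t: "BP" for t in terms}
    root = [t for t in terms if not parents[t]]
    assert len(root) == 1
    return onto.OntologyGraph(graph=graph, aspect=aspect, roots={"BP": root[0]})
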