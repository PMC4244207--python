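"""Gene Ontology DAG handling and semantic-totipotency (T-value) computation.

The ontology is modelled as three rooted DAGs (one per aspect: biological
process BP, molecular function MF, cellular component CC) whose edges point
from child to parent and merge the ``is_a`` and ``part_of`` relations.  Each
term carries a *T-value*, its semantic totipotency: 1 at the aspect root and
attenuated down the hierarchy by a per-edge semantic differentiation factor
``omega`` in (0, 1).  The default omega for an edge (t, p) is the ratio of
descendant counts D(t)/D(p) (descendants including the term itself), which
decreases down the hierarchy and grows with the local density of the term;
alternative rules can be plugged in via ``omega_fn``.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO namespace -> short aspect code
NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

ASPECTS = ("BP", "MF", "CC")

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(Exception):
    """Base class for ontology-related failures."""


class OboParseError(OntologyError):
    """Raised when an OBO file cannot be parsed."""


class StructuralError(OntologyError):
    """Raised when the parsed graph violates the rooted-DAG invariants."""


@dataclass(frozen=True)
class OntologyGraph:
    """A per-aspect single-rooted DAG of ontology terms.

    Attributes
    ----------
    graph : nx.DiGraph
        Directed graph with one edge per (child, parent) pair; ``is_a`` and
        ``part_of`` edges are merged.
    aspect : dict
        Term -> aspect code ("BP", "MF" or "CC").
    roots : dict
        Aspect code -> the unique zero-parent term of that aspect.
    obsolete : frozenset
        Term identifiers excluded as obsolete (they carry no edges).
    """

    graph: nx.DiGraph
    aspect: dict[str, str]
    roots: dict[str, str]
    obsolete: frozenset[str] = frozenset()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by parent edges (excluding itself)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms from which ``term`` is reachable (excluding itself)."""
        return nx.ancestors(self.graph, term)


@dataclass
class TermStats:
    """Per-term descendant counts, T-values and per-edge omega factors."""

    descendant_count: dict[str, int] = field(default_factory=dict)
    t_value: dict[str, float] = field(default_factory=dict)
    omega: dict[tuple[str, str], float] = field(default_factory=dict)


def read_obo(path, keep_relations: Iterable[str] = DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse an OBO file into a per-aspect rooted DAG.

    Only non-obsolete terms are retained.  Of the relationship edges, only
    those named in ``keep_relations`` (default ``is_a`` and ``part_of``) are
    kept; cross-aspect edges are dropped.  Raises :class:`OboParseError` on
    malformed input and :class:`StructuralError` if any aspect subgraph is
    cyclic or not single-rooted.
    """
    keep = frozenset(keep_relations)
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"cannot parse OBO file {path!r}: {exc}") from exc

    obsolete = frozenset(
        n for n, data in multigraph.nodes(data=True)
        if str(data.get("is_obsolete", "false")).lower() == "true"
    )

    aspect: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if node in obsolete:
            continue
        namespace = data.get("namespace")
        if namespace not in NAMESPACE_TO_ASPECT:
            raise OboParseError(
                f"term {node} has missing or unrecognised namespace {namespace!r}"
            )
        aspect[node] = NAMESPACE_TO_ASPECT[namespace]

    graph = nx.DiGraph()
    graph.add_nodes_from(aspect)
    n_dropped_cross = 0
    for child, parent, relation in multigraph.edges(keys=True):
        if relation not in keep:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if aspect.get(child) != aspect.get(parent):
            n_dropped_cross += 1
            continue
        graph.add_edge(child, parent)

    roots: dict[str, str] = {}
    for code in ASPECTS:
        members = [t for t in graph.nodes if aspect[t] == code]
        if not members:
            continue
        sub = graph.subgraph(members)
        if not nx.is_directed_acyclic_graph(sub):
            cycle = nx.find_cycle(sub)
            raise StructuralError(f"aspect {code} subgraph contains a cycle: {cycle}")
        aspect_roots = [t for t in members if sub.out_degree(t) == 0]
        if len(aspect_roots) != 1:
            raise StructuralError(
                f"aspect {code} must have exactly one root, found {sorted(aspect_roots)}"
            )
        roots[code] = aspect_roots[0]

    logger.info(
        "read %d terms, %d parent edges (%d obsolete excluded, %d cross-aspect dropped) from %r",
        graph.number_of_nodes(), graph.number_of_edges(), len(obsolete), n_dropped_cross, path,
    )
    return OntologyGraph(graph=graph, aspect=aspect, roots=roots, obsolete=obsolete)


def descendant_counts(g: OntologyGraph) -> TermStats:
    """Number of descendants of every term, counting the term itself.

    A leaf scores 1; an aspect root scores the size of its aspect.
    """
    stats = TermStats()
    for term in g.graph.nodes:
        stats.descendant_count[term] = len(nx.ancestors(g.graph, term)) + 1
    return stats


def ratio_omega(stats: TermStats, child: str, parent: str) -> float:
    """Default semantic differentiation factor: D(child) / D(parent)."""
    return stats.descendant_count[child] / stats.descendant_count[parent]


def t_values(
    g: OntologyGraph,
    stats: TermStats | None = None,
    omega_fn: Callable[[TermStats, str, str], float] = ratio_omega,
) -> TermStats:
    """Compute semantic totipotency T-values in topological order.

    T(root) = 1 for every aspect root; for any other term
    ``T(t) = mean over parents p of omega(t, p) * T(p)``, so every T-value
    lies in (0, 1) and decreases below the mean of its parents' values.
    """
    if stats is None or not stats.descendant_count:
        stats = descendant_counts(g)

    root_terms = set(g.roots.values())
    orphans = sorted(
        t for t in g.graph.nodes
        if t not in root_terms and g.graph.out_degree(t) == 0
    )
    if orphans:
        raise StructuralError(f"terms unreachable from any aspect root: {orphans}")

    # parents before children: reverse the child->parent topological order
    for term in reversed(list(nx.topological_sort(g.graph))):
        if term in root_terms:
            stats.t_value[term] = 1.0
            continue
        contributions = []
        for parent in g.graph.successors(term):
            w = omega_fn(stats, term, parent)
            stats.omega[(term, parent)] = w
            contributions.append(w * stats.t_value[parent])
        stats.t_value[term] = sum(contributions) / len(contributions)
    return stats


def _up_paths(
    g: OntologyGraph, stats: TermStats, source: str
) -> dict[str, tuple[int, float, tuple[str, ...]]]:
    """Best upward path from ``source`` to every ancestor (and itself).

    Cost order is lexicographic (hop count, summed T-value along the path,
    path term ids), which makes tie-breaking deterministic.
    """
    best: dict[str, tuple[int, float, tuple[str, ...]]] = {}
    heap: list[tuple[int, float, tuple[str, ...]]] = [
        (0, stats.t_value[source], (source,))
    ]
    while heap:
        hops, tsum, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (hops, tsum, path)
        for parent in g.graph.successors(node):
            if parent not in best:
                heapq.heappush(
                    heap, (hops + 1, tsum + stats.t_value[parent], path + (parent,))
                )
    return best


def lca_shortest_path(
    g: OntologyGraph, stats: TermStats, t1: str, t2: str
) -> list[str]:
    """Shortest path t1 -> LCA -> t2 through a lowest common ancestor.

    Among candidate common ancestors the path with the fewest hops is chosen;
    ties are broken by the minimal summed T-value and then by term identifier,
    so ``lca_shortest_path(t2, t1)`` is exactly the reverse.
    """
    for t in (t1, t2):
        if t not in g:
            raise KeyError(f"term {t} not in ontology")
    if g.aspect[t1] != g.aspect[t2]:
        raise ValueError(
            f"terms {t1} ({g.aspect[t1]}) and {t2} ({g.aspect[t2]}) are in different aspects"
        )
    if t1 == t2:
        return [t1]

    up1 = _up_paths(g, stats, t1)
    up2 = _up_paths(g, stats, t2)
    common = set(up1) & set(up2)
    assert common, "single-rooted aspect guarantees a common ancestor"

    def cost(anc: str) -> tuple[int, float, str]:
        h1, s1, _ = up1[anc]
        h2, s2, _ = up2[anc]
        # the ancestor's own T-value is counted once
        return (h1 + h2, s1 + s2 - stats.t_value[anc], anc)

    lca = min(common, key=cost)
    path_up = list(up1[lca][2])
    path_down = list(up2[lca][2])[:-1][::-1]
    return path_up + path_down


def write_term_stats(g: OntologyGraph, stats: TermStats, path) -> None:
    """Dump ``term<TAB>aspect<TAB>descendant_count<TAB>t_value`` rows."""
    with open(path, "w") as fh:
        fh.write("term\taspect\tdescendant_count\tt_value\n")
        for term in sorted(g.graph.nodes):
            fh.write(
                f"{term}\t{g.aspect[term]}\t{stats.descendant_count[term]}\t"
                f"{stats.t_value[term]:.10g}\n"
            )
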