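"""Guilt-by-association candidate discovery and weighted-rating prioritization.

Candidates are the direct network neighbours of a set of function-known query
genes.  Within the largest module containing queries and candidates, each
candidate is scored by the IMDb-style "true Bayesian estimate"
``WR = v/(v+m) * F + m/(v+m) * C`` where ``v`` is its number of adjacent
query genes, ``F`` the mean weight of its edges to them, ``C`` the mean F
over all candidates, and ``m`` the first quartile of the candidates' ``v``
distribution — a shrinkage of F toward the global mean for candidates with
few supporting queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from gofnet.network import WeightedGeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class CandidateRanking:
    """Ranked candidates with their WR-score ingredients."""

    table: pd.DataFrame  # columns: gene, v, F, wr, rank
    m: float
    C: float


@dataclass
class ClassificationSummary:
    """Counts and percentages of candidates by status."""

    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    total: int = 0
    n_known: int = 0
    n_identified: int = 0
    percent_increase: float | None = None


def _graph_of(net: WeightedGeneNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, WeightedGeneNetwork) else net


def gba_candidates(
    net: WeightedGeneNetwork | nx.Graph, queries: set[str]
) -> set[str]:
    """Direct-neighbour candidates: union of query neighbourhoods minus queries."""
    graph = _graph_of(net)
    present = {q for q in queries if q in graph}
    missing = set(queries) - present
    if missing:
        logger.warning("%d query genes absent from network: %s",
                       len(missing), sorted(missing)[:10])
    if not present:
        raise ValueError("no query gene is present in the network")
    candidates: set[str] = set()
    for q in present:
        candidates.update(graph.neighbors(q))
    return candidates - set(queries)


def extract_module(
    net: WeightedGeneNetwork | nx.Graph,
    queries: set[str],
    candidates: set[str],
) -> tuple[WeightedGeneNetwork, set[str]]:
    """Largest connected component of the induced query+candidate subgraph.

    Returns the component as a network plus the query genes it contains.
    """
    graph = _graph_of(net)
    members = (set(queries) | set(candidates)) & set(graph.nodes)
    induced = graph.subgraph(members)
    if induced.number_of_nodes() == 0:
        return WeightedGeneNetwork(graph=nx.Graph()), set()
    largest = max(nx.connected_components(induced), key=lambda c: (len(c), sorted(c)))
    module = nx.Graph(induced.subgraph(largest))
    aspect = net.aspect if isinstance(net, WeightedGeneNetwork) else "INT"
    return (
        WeightedGeneNetwork(graph=module, aspect=aspect),
        set(queries) & set(module.nodes),
    )


def weighted_rating(v: float, f: float, m: float, c: float) -> float:
    """True-Bayesian-estimate weighted rating: v/(v+m)*F + m/(v+m)*C."""
    return (v / (v + m)) * f + (m / (v + m)) * c


def wr_scores(
    module: WeightedGeneNetwork | nx.Graph, queries: set[str]
) -> CandidateRanking:
    """Weighted-rating prioritization of the module's candidate genes.

    ``m`` is the first quartile (linear-interpolation) of the candidates'
    query-neighbour counts; candidates with no query neighbour inside the
    module are excluded with a warning.  Ties in WR break lexicographically
    by gene id.
    """
    graph = _graph_of(module)
    queries_in = set(queries) & set(graph.nodes)
    if not queries_in:
        raise ValueError("module contains no query gene")

    rows = []
    for gene in sorted(set(graph.nodes) - set(queries)):
        q_neighbours = [q for q in graph.neighbors(gene) if q in queries_in]
        if not q_neighbours:
            logger.warning("candidate %s has no query neighbour in module; excluded", gene)
            continue
        weights = [graph[gene][q].get("weight", 1.0) for q in q_neighbours]
        rows.append({"gene": gene, "v": len(q_neighbours), "F": float(np.mean(weights))})
    if not rows:
        raise ValueError("no candidate with a query neighbour in the module")

    df = pd.DataFrame(rows)
    m = float(np.percentile(df["v"], 25))
    c = float(df["F"].mean())
    df["wr"] = weighted_rating(df["v"], df["F"], m, c)
    df = df.sort_values(["wr", "gene"], ascending=[False, True], ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return CandidateRanking(table=df, m=m, C=c)


def classification_summary(
    candidates,
    status_labels: dict[str, str],
    known_statuses: set[str] = frozenset({"known"}),
    identified_statuses: set[str] = frozenset({"known", "newly_predicted"}),
) -> ClassificationSummary:
    """Count candidates by status with percentages to 2 decimals.

    The percent increase compares the identified statuses (e.g. known plus
    newly predicted) against the previously known ones, to 1 decimal.
    """
    candidates = list(candidates)
    missing = [g for g in candidates if g not in status_labels]
    if missing:
        raise ValueError(f"unlabelled candidates: {missing[:10]}")
    summary = ClassificationSummary(total=len(candidates))
    for gene in candidates:
        status = status_labels[gene]
        summary.counts[status] = summary.counts.get(status, 0) + 1
    for status, count in summary.counts.items():
        summary.percentages[status] = round(100.0 * count / summary.total, 2)
    summary.n_known = sum(
        c for s, c in summary.counts.items() if s in known_statuses
    )
    summary.n_identified = sum(
        c for s, c in summary.counts.items() if s in identified_statuses
    )
    if summary.n_known > 0:
        summary.percent_increase = round(
            100.0 * (summary.n_identified - summary.n_known) / summary.n_known, 1
        )
    return summary


def smoothed_gba_scores(
    net: WeightedGeneNetwork | nx.Graph, queries: set[str], alpha: float = 1.0
) -> dict[str, float]:
    """Optional extension: one-step weight-normalised label diffusion.

    Queries carry label 1; every other node receives ``alpha`` times the
    weight-normalised mean label of its neighbours.  The default direct
    -neighbour GBA (:func:`gba_candidates`) is the primary discovery route;
    this smoother only grades candidates continuously.
    """
    graph = _graph_of(net)
    queries_in = set(queries) & set(graph.nodes)
    scores: dict[str, float] = {}
    for node in graph.nodes:
        if node in queries_in:
            continue
        total = sum(graph[node][n].get("weight", 1.0) for n in graph.neighbors(node))
        if total == 0.0:
            scores[node] = 0.0
            continue
        hit = sum(
            graph[node][n].get("weight", 1.0)
            for n in graph.neighbors(node)
            if n in queries_in
        )
        scores[node] = alpha * hit / total
    return scores
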