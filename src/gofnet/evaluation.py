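"""Reference-network construction and coverage/accuracy validation.

A query gene network is validated against an independent reference network
(shared-pathway cliques, co-expression, or orthology transfer) through two
statistics: gene coverage ``Cg = 100 * Ns / Nk`` (shared genes over reference
genes) and linkage accuracy ``La`` (the fraction of the query's edges among
shared genes that the reference confirms).  Significance is assessed against
degree-preserving randomizations of the query network (double-edge swaps):
the observed La is ranked within the background La distribution.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from gofnet.network import WeightedGeneNetwork

logger = logging.getLogger(__name__)


@dataclass
class ReferenceNetwork:
    """Unweighted reference network with its provenance kind."""

    kind: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ValidationReport:
    """Coverage/accuracy of a query network against a reference."""

    n_shared_genes: int = 0
    n_reference_genes: int = 0
    gene_coverage_pct: float | None = None
    n_query_links_shared: int = 0
    n_reference_links: int = 0
    linkage_accuracy_pct: float | None = None
    background_mean_accuracy: float | None = None
    background_sd_accuracy: float | None = None
    p_value: float | None = None
    flags: list[str] = field(default_factory=list)


def _read_two_column(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            pairs.append((cols[0], cols[1]))
    return pairs


def kegg_reference(links) -> ReferenceNetwork:
    """Clique-expand a gene -> pathway-term link table.

    Genes sharing at least one term are linked; cliques from different terms
    union and deduplicate.  ``links`` is a path to a two-column TSV or an
    iterable of (gene, term) pairs.
    """
    if isinstance(links, (str, Path)):
        links = _read_two_column(links)
    by_term: dict[str, list[str]] = {}
    for gene, term in links:
        members = by_term.setdefault(term, [])
        if gene not in members:
            members.append(gene)
    graph = nx.Graph()
    for members in by_term.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a != b:
                    graph.add_edge(a, b)
    return ReferenceNetwork(kind="kegg", graph=graph)


def coexpression_reference(
    datasets: Sequence[pd.DataFrame],
    min_samples: int = 20,
    pcc_cutoff: float = 0.8,
) -> ReferenceNetwork:
    """Union of per-dataset co-expression edges at |PCC| strictly above cutoff.

    Each dataset is a genes x samples matrix (gene ids on the index).
    Datasets with fewer than ``min_samples`` columns are discarded; genes with
    constant expression have an undefined correlation and are skipped with a
    warning.
    """
    graph = nx.Graph()
    n_used = 0
    for idx, df in enumerate(datasets):
        if df.shape[1] < min_samples:
            logger.info("dataset %d dropped: %d < %d samples", idx, df.shape[1], min_samples)
            continue
        n_used += 1
        values = df.to_numpy(dtype=float)
        genes = list(df.index)
        sd = values.std(axis=1)
        constant = sd == 0.0
        if constant.any():
            logger.warning(
                "dataset %d: %d constant-expression genes skipped", idx, int(constant.sum())
            )
        keep = ~constant
        kept_genes = [g for g, k in zip(genes, keep) if k]
        if len(kept_genes) < 2:
            continue
        corr = np.corrcoef(values[keep])
        hit_i, hit_j = np.where(np.triu(np.abs(corr) > pcc_cutoff, k=1))
        for i, j in zip(hit_i, hit_j):
            if kept_genes[i] != kept_genes[j]:
                graph.add_edge(kept_genes[i], kept_genes[j])
    logger.info("co-expression reference from %d datasets: %d nodes, %d edges",
                n_used, graph.number_of_nodes(), graph.number_of_edges())
    return ReferenceNetwork(kind="coexpression", graph=graph)


def orthology_transfer(
    source_edges: Iterable[tuple[str, str]],
    orthologs: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
) -> ReferenceNetwork:
    """Transfer source-species edges through an ortholog map (one-to-many).

    Every source edge (a, b) yields every (a', b') with a' an ortholog of a
    and b' of b; pairs collapsing onto a single target gene are dropped.
    ``orthologs`` is a mapping or an iterable of (source, target) pairs.
    """
    if not isinstance(orthologs, Mapping):
        built: dict[str, list[str]] = {}
        for src, tgt in orthologs:
            built.setdefault(src, []).append(tgt)
        orthologs = built
    graph = nx.Graph()
    for a, b in source_edges:
        for a2 in orthologs.get(a, ()):
            for b2 in orthologs.get(b, ()):
                if a2 != b2:
                    graph.add_edge(a2, b2)
    return ReferenceNetwork(kind="orthology", graph=graph)


def _as_graph(obj) -> nx.Graph:
    if isinstance(obj, (WeightedGeneNetwork, ReferenceNetwork)):
        return obj.graph
    return obj


def coverage_pct(n_shared: int, n_reference: int) -> float:
    """Gene coverage Cg = 100 * Ns / Nk, to 2 decimals."""
    if n_reference <= 0:
        raise ValueError("reference gene count must be positive")
    return round(100.0 * n_shared / n_reference, 2)


def accuracy_pct(n_confirmed: int, n_total: int) -> float:
    """Linkage accuracy La = 100 * Ls / Lk, to 2 decimals."""
    if n_total <= 0:
        raise ValueError("link denominator must be positive")
    return round(100.0 * n_confirmed / n_total, 2)


def coverage_accuracy(
    query: WeightedGeneNetwork | nx.Graph,
    ref: ReferenceNetwork | nx.Graph,
    literal_la: bool = False,
) -> ValidationReport:
    """Gene coverage and linkage accuracy of a query network vs a reference.

    Default La: of the query's edges whose endpoints are both shared genes
    (``Lk``), the fraction also present in the reference (``Ls``), as a
    percentage — bounded by 100.  The literal variant instead divides the
    query's shared-gene edge count by the reference's shared-gene edge count.
    Percentages are reported to 2 decimals.
    """
    q_graph = _as_graph(query)
    r_graph = _as_graph(ref)

    shared = set(q_graph.nodes) & set(r_graph.nodes)
    report = ValidationReport(
        n_shared_genes=len(shared),
        n_reference_genes=r_graph.number_of_nodes(),
    )
    if report.n_reference_genes == 0:
        report.flags.append("empty reference: Cg undefined")
    else:
        report.gene_coverage_pct = coverage_pct(len(shared), report.n_reference_genes)

    q_shared_edges = [
        (u, v) for u, v in q_graph.edges() if u in shared and v in shared
    ]
    if literal_la:
        ls = len(q_shared_edges)
        lk = sum(1 for u, v in r_graph.edges() if u in shared and v in shared)
    else:
        ls = sum(1 for u, v in q_shared_edges if r_graph.has_edge(u, v))
        lk = len(q_shared_edges)
    report.n_query_links_shared = ls
    report.n_reference_links = lk
    if lk == 0:
        report.flags.append("no shared-gene links: La undefined")
    else:
        report.linkage_accuracy_pct = accuracy_pct(ls, lk)
    return report


def rewire(
    graph: nx.Graph,
    rng: random.Random | int | None = None,
    swaps_per_edge: int = 10,
) -> nx.Graph:
    """One degree-preserving randomization by accepted double-edge swaps.

    Performs ``swaps_per_edge * |E|`` accepted swaps, rejecting any that
    would create a self-loop or multi-edge, so every node's degree is
    preserved exactly.
    """
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    rewired = graph.copy()
    nswap = swaps_per_edge * rewired.number_of_edges()
    nx.double_edge_swap(rewired, nswap=nswap, max_tries=100 * nswap, seed=rng)
    return rewired


@dataclass
class BackgroundResult:
    """Randomized-background linkage accuracy and empirical significance."""

    observed_la: float
    background_mean: float
    background_sd: float
    p_value: float
    replicates: list[float] = field(default_factory=list)


def randomized_background(
    query: WeightedGeneNetwork | nx.Graph,
    ref: ReferenceNetwork | nx.Graph,
    n_random: int = 400,
    seed: int | None = None,
    swaps_per_edge: int = 10,
    literal_la: bool = False,
) -> BackgroundResult:
    """Degree-preserving rewiring null for the linkage accuracy.

    Each of ``n_random`` replicates rewires the query by accepted double-edge
    swaps (``swaps_per_edge * |E|`` of them), preserving every node's degree,
    then recomputes La against the reference.  The p-value is the one-sided
    add-one-corrected rank of the observed La in the background sample.
    """
    q_graph = _as_graph(query)
    if q_graph.number_of_edges() < 2:
        raise ValueError("randomized background requires a query with >= 2 edges")

    observed = coverage_accuracy(q_graph, ref, literal_la=literal_la).linkage_accuracy_pct
    if observed is None:
        raise ValueError("observed linkage accuracy undefined; cannot build background")

    rng = random.Random(seed)
    replicates: list[float] = []
    for _ in range(n_random):
        try:
            rewired = rewire(q_graph, rng=rng, swaps_per_edge=swaps_per_edge)
        except nx.NetworkXError as exc:
            logger.warning("rewiring impossible (%s); background equals observed", exc)
            replicates.append(observed)
            continue
        la = coverage_accuracy(rewired, ref, literal_la=literal_la).linkage_accuracy_pct
        replicates.append(la if la is not None else 0.0)

    arr = np.asarray(replicates, dtype=float)
    n_ge = int(np.sum(arr >= observed))
    return BackgroundResult(
        observed_la=observed,
        background_mean=float(arr.mean()),
        background_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        p_value=(n_ge + 1) / (len(arr) + 1),
        replicates=replicates,
    )


def anova_significance(backgrounds: Sequence[BackgroundResult]) -> float:
    """One-way ANOVA p across the background La samples of several networks.

    Offered for the multi-network comparison setting; the single-network
    default significance is the empirical rank p in
    :func:`randomized_background`.
    """
    if len(backgrounds) < 2:
        raise ValueError("ANOVA requires at least two networks")
    groups = [b.replicates for b in backgrounds]
    return float(scipy_stats.f_oneway(*groups).pvalue)
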