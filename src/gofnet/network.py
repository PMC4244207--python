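"""Thresholded weighted gene networks and clustering-coefficient-gap selection.

A functional gene network keeps every gene pair whose similarity is at least
a threshold; the threshold itself is chosen by scanning a 0.01-step grid and
taking the first stop of the monotonic increase of
``delta = C_obs - C_rand``, where ``C_obs`` is the network's mean clustering
coefficient and ``C_rand`` the configuration-model expectation for its degree
sequence.  A genuine modular network peaks well above its random expectation;
past the peak the threshold starts dismantling real modules.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from gofnet.similarity import GeneSimilarity

logger = logging.getLogger(__name__)

_WEIGHT_FIELD = {"BP": "s_bp", "MF": "s_mf", "CC": "s_cc", "INT": "s_int"}


@dataclass
class WeightedGeneNetwork:
    """Undirected weighted gene network with threshold provenance."""

    graph: nx.Graph
    threshold: float = 0.0
    aspect: str = "INT"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ThresholdScanResult:
    """Per-threshold clustering statistics and the selected cutoff."""

    grid: list[float] = field(default_factory=list)
    c_obs: list[float] = field(default_factory=list)
    c_rand: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    node_count: list[int] = field(default_factory=list)
    edge_count: list[int] = field(default_factory=list)
    selected: float = float("nan")
    hit_grid_end: bool = False


def _pair_weight(record: GeneSimilarity, aspect: str) -> float:
    return getattr(record, _WEIGHT_FIELD[aspect])


def build_network(
    pairs: Iterable[GeneSimilarity], aspect: str = "INT", threshold: float = 0.0
) -> WeightedGeneNetwork:
    """Keep each pair as an edge iff its similarity is >= ``threshold``.

    Zero-similarity pairs never become edges, and genes left without any
    surviving edge are excluded, so node counts shrink with the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    graph = nx.Graph()
    for record in pairs:
        if record.gene_a == record.gene_b:
            continue
        weight = _pair_weight(record, aspect)
        if weight > 0.0 and weight >= threshold:
            graph.add_edge(record.gene_a, record.gene_b, weight=weight)
    return WeightedGeneNetwork(graph=graph, threshold=threshold, aspect=aspect)


def clustering_coefficient(net: WeightedGeneNetwork | nx.Graph) -> float:
    """Mean of the per-node clustering coefficients (0 for degree < 2 nodes)."""
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    if graph.number_of_nodes() == 0:
        return 0.0
    local = nx.clustering(graph)
    return sum(local.values()) / len(local)


def random_clustering_expectation(net: WeightedGeneNetwork | nx.Graph) -> float:
    """Configuration-model expectation of the clustering coefficient.

    For degree sequence k over N nodes: (<k^2> - <k>)^2 / (N * <k>^3).
    Returns 0 for an empty graph or zero mean degree.
    """
    graph = net.graph if isinstance(net, WeightedGeneNetwork) else net
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    k = np.fromiter((d for _, d in graph.degree()), dtype=float, count=n)
    mean_k = k.mean()
    if mean_k == 0.0:
        return 0.0
    mean_k2 = (k * k).mean()
    return (mean_k2 - mean_k) ** 2 / (n * mean_k ** 3)


def threshold_scan(
    pairs: Iterable[GeneSimilarity], aspect: str = "INT"
) -> ThresholdScanResult:
    """Scan thresholds 0.00..1.00 (step 0.01) and select the first delta-C stop.

    ``delta(t) = C_obs(t) - C_rand(t)`` is recorded on the whole grid; the
    selected threshold is the smallest t >= 0.01 with
    ``delta(t) >= delta(t + 0.01)`` — the point where the increasing run of
    delta stops (plateaus count as stops).  If delta still increases at the
    grid end, 1.00 is returned with a warning.
    """
    records = list(pairs)
    if not records or all(_pair_weight(r, aspect) == 0.0 for r in records):
        raise ValueError(f"all {aspect} similarities are zero; nothing to scan")

    result = ThresholdScanResult()
    grid = [round(i / 100.0, 2) for i in range(101)]
    for t in grid:
        net = build_network(records, aspect=aspect, threshold=t)
        c_obs = clustering_coefficient(net)
        c_rand = random_clustering_expectation(net)
        result.grid.append(t)
        result.c_obs.append(c_obs)
        result.c_rand.append(c_rand)
        result.delta.append(c_obs - c_rand)
        result.node_count.append(net.n_nodes)
        result.edge_count.append(net.n_edges)

    result.selected, result.hit_grid_end = select_first_stop(result.delta, grid)
    if result.hit_grid_end:
        logger.warning("delta-C increases through the whole grid; selected %.2f", result.selected)
    return result


def select_first_stop(delta: Sequence[float], grid: Sequence[float]) -> tuple[float, bool]:
    """First stop of the monotonic increase of delta along the grid.

    Returns the smallest grid value t (from the second grid point on) with
    ``delta(t) >= delta(next t)`` — a peak or the start of a plateau.  If
    delta still rises at the end of the grid the last grid point is returned
    with the ``hit_grid_end`` flag set.
    """
    for i in range(1, len(grid) - 1):
        if delta[i] >= delta[i + 1]:
            return grid[i], False
    return grid[-1], True


def global_properties(net: WeightedGeneNetwork) -> dict:
    """Summary topology report of a network.

    Diameter, radius and characteristic path length are computed on the
    largest connected component; heterogeneity is the coefficient of
    variation of the degree sequence.
    """
    graph = net.graph
    n = graph.number_of_nodes()
    props: dict = {
        "nodes": n,
        "edges": graph.number_of_edges(),
        "clustering_coefficient": clustering_coefficient(net),
        "connected_components": nx.number_connected_components(graph) if n else 0,
    }
    if n == 0:
        props.update(
            diameter=0, radius=0, characteristic_path_length=0.0,
            mean_neighbors=0.0, density=0.0, centralisation=0.0, heterogeneity=0.0,
        )
        return props

    largest = graph.subgraph(max(nx.connected_components(graph), key=len))
    if largest.number_of_nodes() > 1:
        ecc = nx.eccentricity(largest)
        props["diameter"] = max(ecc.values())
        props["radius"] = min(ecc.values())
        props["characteristic_path_length"] = nx.average_shortest_path_length(largest)
    else:
        props["diameter"] = 0
        props["radius"] = 0
        props["characteristic_path_length"] = 0.0

    degrees = np.fromiter((d for _, d in graph.degree()), dtype=float, count=n)
    mean_k = degrees.mean()
    props["mean_neighbors"] = float(mean_k)
    props["density"] = nx.density(graph)
    if n > 2:
        props["centralisation"] = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        props["centralisation"] = 0.0
    props["heterogeneity"] = float(degrees.std() / mean_k) if mean_k > 0 else 0.0
    return props


def write_edge_list(net: WeightedGeneNetwork, path) -> None:
    """Weighted edge-list TSV: ``gene_a<TAB>gene_b<TAB>weight``."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            a, b = sorted((a, b))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.8g}\n")


def read_edge_list(path, aspect: str = "INT", threshold: float = 0.0) -> WeightedGeneNetwork:
    """Read the weighted edge-list TSV produced by :func:`write_edge_list`."""
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if line.startswith("gene_a\t") or not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            graph.add_edge(a, b, weight=float(w))
    return WeightedGeneNetwork(graph=graph, threshold=threshold, aspect=aspect)


def write_sif(net: WeightedGeneNetwork, path, interaction: str = "fs") -> None:
    """Simple interaction format: ``gene_a interaction gene_b`` rows."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_scan_result(result: ThresholdScanResult, tsv_path, json_path=None) -> None:
    """Scan table as TSV plus an optional JSON summary with ``selected``."""
    with open(tsv_path, "w") as fh:
        fh.write("threshold\tnodes\tedges\tc_obs\tc_rand\tdelta\n")
        for i, t in enumerate(result.grid):
            fh.write(
                f"{t:.2f}\t{result.node_count[i]}\t{result.edge_count[i]}\t"
                f"{result.c_obs[i]:.8g}\t{result.c_rand[i]:.8g}\t{result.delta[i]:.8g}\n"
            )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "selected": result.selected,
                    "hit_grid_end": result.hit_grid_end,
                    "max_delta": max(result.delta) if result.delta else math.nan,
                },
                fh,
                indent=2,
            )
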