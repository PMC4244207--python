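"""SSDD term similarity, best-match-average gene similarity, aspect integration.

The shortest semantic differentiation distance (SSDD) between two terms sums
the T-values of the terms on the shortest DAG path joining them through a
lowest common ancestor, normalised to (0, 1) with (2/pi)*arctan; the
similarity is one minus that distance.  Gene-level similarity per aspect is
the best-match average (BMA) over the two genes' term sets, and the three
aspect similarities integrate into a single score by a similarity-weighted
average, so an aspect contributes in proportion to how similar the genes
already are in it — a zero aspect cannot drag the integrated value to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from gofnet.annotation import AnnotationSet
from gofnet.ontology import ASPECTS, OntologyGraph, TermStats, lca_shortest_path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermSimilarity:
    """Normalised SSDD distance and its complement similarity."""

    distance: float
    similarity: float


@dataclass(frozen=True)
class GeneSimilarity:
    """Per-aspect and integrated functional similarity of one gene pair."""

    gene_a: str
    gene_b: str
    s_bp: float
    s_mf: float
    s_cc: float
    s_int: float


def pair_count(n: int) -> int:
    """Number of unordered pairs of ``n`` items: n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def ssdd_similarity(
    g: OntologyGraph,
    stats: TermStats,
    t1: str,
    t2: str,
    identical_term_sim_one: bool = False,
) -> TermSimilarity:
    """SSDD similarity between two terms of the same aspect.

    distance = (2/pi) * arctan(sum of T-values over the shortest LCA path);
    similarity = 1 - distance.  Under the literal path rule the degenerate
    path of an identical pair is the single term itself, so self-similarity is
    below 1; set ``identical_term_sim_one`` to force self-similarity to 1.
    Cross-aspect pairs are flagged and scored 0.
    """
    if g.aspect[t1] != g.aspect[t2]:
        logger.warning("cross-aspect term pair (%s, %s): similarity 0", t1, t2)
        return TermSimilarity(distance=1.0, similarity=0.0)
    if identical_term_sim_one and t1 == t2:
        return TermSimilarity(distance=0.0, similarity=1.0)
    path = lca_shortest_path(g, stats, t1, t2)
    total_t = sum(stats.t_value[t] for t in path)
    distance = (2.0 / math.pi) * math.atan(total_t)
    return TermSimilarity(distance=distance, similarity=1.0 - distance)


class TermPairCache:
    """Memoises SSDD similarities keyed on the unordered term pair."""

    def __init__(
        self,
        g: OntologyGraph,
        stats: TermStats,
        identical_term_sim_one: bool = False,
    ):
        self.g = g
        self.stats = stats
        self.identical_term_sim_one = identical_term_sim_one
        self._cache: dict[tuple[str, str], float] = {}

    def similarity(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        value = self._cache.get(key)
        if value is None:
            value = ssdd_similarity(
                self.g, self.stats, t1, t2, self.identical_term_sim_one
            ).similarity
            self._cache[key] = value
        return value

    def __len__(self) -> int:
        return len(self._cache)


def bma_gene_similarity(
    g: OntologyGraph,
    stats: TermStats,
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    cache: TermPairCache | None = None,
    identical_term_sim_one: bool = False,
) -> float:
    """Best-match-average similarity of two term sets.

    Each term of the first set is paired with its most similar term of the
    second set and vice versa; the two directional means are averaged.  An
    empty set on either side yields 0 (logged, not an error).
    """
    set_a, set_b = list(terms_a), list(terms_b)
    if not set_a or not set_b:
        logger.debug("empty term set in BMA; aspect similarity 0")
        return 0.0
    if cache is None:
        cache = TermPairCache(g, stats, identical_term_sim_one)
    best_a = [max(cache.similarity(a, b) for b in set_b) for a in set_a]
    best_b = [max(cache.similarity(a, b) for a in set_a) for b in set_b]
    return 0.5 * (sum(best_a) / len(best_a) + sum(best_b) / len(best_b))


def integrate_aspects(s_bp: float, s_mf: float, s_cc: float) -> float:
    """Similarity-weighted average of the three aspect similarities.

    s_int = (s_bp^2 + s_mf^2 + s_cc^2) / (s_bp + s_mf + s_cc); each aspect
    weight equals its own similarity, and the result lies between the minimum
    and maximum of the nonzero inputs.  All-zero input yields 0.
    """
    values = (s_bp, s_mf, s_cc)
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"aspect similarity {v} outside [0, 1]")
    total = sum(values)
    if total == 0.0:
        return 0.0
    return sum(v * v for v in values) / total


def all_pairs_similarity(
    g: OntologyGraph,
    stats: TermStats,
    ann: AnnotationSet,
    aspect: str = "INT",
    identical_term_sim_one: bool = False,
    cache: TermPairCache | None = None,
) -> Iterator[GeneSimilarity]:
    """Stream the similarity of every unordered gene pair exactly once.

    The gene universe is the genes annotated in ``aspect`` for BP/MF/CC, or
    the union of all annotated genes for INT.  Pairs are emitted in sorted
    (gene_a, gene_b) order with gene_a < gene_b, so output files are
    deterministic; term-pair similarities are cached across pairs.
    """
    if aspect == "INT":
        universe = sorted(ann.gene_universe)
    elif aspect in ASPECTS:
        universe = sorted(ann.by_aspect[aspect])
    else:
        raise ValueError(f"unknown aspect selector {aspect!r}")

    if cache is None:
        cache = TermPairCache(g, stats, identical_term_sim_one)

    for i, gene_a in enumerate(universe):
        for gene_b in universe[i + 1:]:
            per_aspect = {}
            for code in ASPECTS:
                per_aspect[code] = bma_gene_similarity(
                    g, stats,
                    ann.terms_of(gene_a, code),
                    ann.terms_of(gene_b, code),
                    cache=cache,
                )
            yield GeneSimilarity(
                gene_a=gene_a,
                gene_b=gene_b,
                s_bp=per_aspect["BP"],
                s_mf=per_aspect["MF"],
                s_cc=per_aspect["CC"],
                s_int=integrate_aspects(
                    per_aspect["BP"], per_aspect["MF"], per_aspect["CC"]
                ),
            )


def write_similarity_tsv(records: Iterable[GeneSimilarity], path, comment: str = "") -> None:
    """Write ``gene_a gene_b s_bp s_mf s_cc s_int`` rows (tab-separated)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("gene_a\tgene_b\ts_bp\ts_mf\ts_cc\ts_int\n")
        for r in records:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{r.s_bp:.8g}\t{r.s_mf:.8g}\t"
                f"{r.s_cc:.8g}\t{r.s_int:.8g}\n"
            )


def read_similarity_tsv(path) -> list[GeneSimilarity]:
    """Read the TSV produced by :func:`write_similarity_tsv`."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene_a\t"):
                continue
            a, b, bp, mf, cc, integrated = line.rstrip("\n").split("\t")
            records.append(
                GeneSimilarity(a, b, float(bp), float(mf), float(cc), float(integrated))
            )
    return records
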