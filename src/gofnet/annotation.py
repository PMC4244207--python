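"""GAF annotation parsing into per-aspect gene -> term-set maps.

Reads tab-separated Gene Association Files (GAF 2.x), with optional evidence
-code exclusion and NOT-qualifier dropping, and maps the one-letter aspect
column (P/F/C) to the BP/MF/CC codes used throughout the package.  All
evidence codes, including IEA, are kept by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from gofnet.ontology import ASPECTS, OntologyGraph

logger = logging.getLogger(__name__)

GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

#: minimum column count of a GAF 2.x body row
_GAF_MIN_COLUMNS = 15

_COL_GENE = 1
_COL_QUALIFIER = 3
_COL_TERM = 4
_COL_EVIDENCE = 6
_COL_ASPECT = 8


class GafParseError(Exception):
    """Raised on malformed GAF rows, carrying the offending line number."""


@dataclass
class AnnotationSet:
    """Per-aspect gene -> set-of-terms maps with provenance."""

    by_aspect: dict[str, dict[str, set[str]]] = field(
        default_factory=lambda: {a: {} for a in ASPECTS}
    )
    provenance: dict = field(default_factory=dict)

    @property
    def gene_universe(self) -> set[str]:
        """Union of the genes annotated in any aspect."""
        universe: set[str] = set()
        for genes in self.by_aspect.values():
            universe.update(genes)
        return universe

    def terms_of(self, gene: str, aspect: str) -> set[str]:
        return self.by_aspect.get(aspect, {}).get(gene, set())


def read_gaf(
    path,
    evidence_exclude: Iterable[str] = (),
    drop_not_qualifier: bool = True,
    ontology: OntologyGraph | None = None,
) -> AnnotationSet:
    """Parse a GAF 2.x file.

    Comment lines start with ``!``.  Column 2 is the gene identifier, column 5
    the term, column 7 the evidence code and column 9 the one-letter aspect.
    Rows whose qualifier contains ``NOT`` are dropped when
    ``drop_not_qualifier`` is set (the default); duplicate (gene, term) pairs
    collapse.  If ``ontology`` is given, annotations to terms absent from it
    (or recorded under a different aspect) are dropped with a warning.
    """
    excluded = frozenset(evidence_exclude)
    ann = AnnotationSet(
        provenance={
            "source": str(path),
            "evidence_exclude": sorted(excluded),
            "drop_not_qualifier": drop_not_qualifier,
        }
    )
    n_rows = n_not = n_evidence = n_missing = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < _GAF_MIN_COLUMNS:
                raise GafParseError(
                    f"{path}:{lineno}: expected >= {_GAF_MIN_COLUMNS} columns, got {len(cols)}"
                )
            gene, qualifier = cols[_COL_GENE], cols[_COL_QUALIFIER]
            term, evidence, aspect_code = cols[_COL_TERM], cols[_COL_EVIDENCE], cols[_COL_ASPECT]
            if aspect_code not in GAF_ASPECT:
                raise GafParseError(
                    f"{path}:{lineno}: unknown aspect code {aspect_code!r}"
                )
            n_rows += 1
            if drop_not_qualifier and "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if evidence in excluded:
                n_evidence += 1
                continue
            aspect = GAF_ASPECT[aspect_code]
            if ontology is not None and (
                term not in ontology or ontology.aspect[term] != aspect
            ):
                n_missing += 1
                logger.warning(
                    "%s:%d: term %s absent from ontology (or aspect mismatch); dropped",
                    path, lineno, term,
                )
                continue
            ann.by_aspect[aspect].setdefault(gene, set()).add(term)
    logger.info(
        "read %d annotation rows from %r (%d NOT-qualified, %d evidence-excluded, "
        "%d unknown-term dropped)",
        n_rows, path, n_not, n_evidence, n_missing,
    )
    return ann


def map_identifiers(
    ann: AnnotationSet,
    mapping: Mapping[str, str],
    drop_unmapped: bool = False,
) -> AnnotationSet:
    """Translate gene identifiers through a (many-to-one) mapping table.

    When two source identifiers map to the same target the term sets merge.
    Unmapped genes are kept under their original id, or removed entirely when
    ``drop_unmapped`` is set.
    """
    if not mapping:
        raise ValueError("identifier mapping is empty")
    out = AnnotationSet(provenance={**ann.provenance, "id_mapping": True})
    for aspect, genes in ann.by_aspect.items():
        target_map = out.by_aspect[aspect]
        for gene, terms in genes.items():
            if gene in mapping:
                new_id = mapping[gene]
            elif drop_unmapped:
                continue
            else:
                new_id = gene
            target_map.setdefault(new_id, set()).update(terms)
    return out


def annotation_summary(ann: AnnotationSet) -> dict:
    """Per-aspect gene and (gene, term) entry counts, plus totals."""
    summary = {}
    total_entries = 0
    for aspect in ASPECTS:
        genes = ann.by_aspect.get(aspect, {})
        entries = sum(len(terms) for terms in genes.values())
        summary[aspect] = {"genes": len(genes), "entries": entries}
        total_entries += entries
    summary["total"] = {"genes": len(ann.gene_universe), "entries": total_entries}
    return summary


def write_tsv(ann: AnnotationSet, path) -> None:
    """Write sorted ``gene<TAB>aspect<TAB>term`` rows."""
    with open(path, "w") as fh:
        fh.write("gene\taspect\tterm\n")
        for aspect in ASPECTS:
            for gene in sorted(ann.by_aspect.get(aspect, {})):
                for term in sorted(ann.by_aspect[aspect][gene]):
                    fh.write(f"{gene}\t{aspect}\t{term}\n")


def read_tsv(path) -> AnnotationSet:
    """Read the TSV produced by :func:`write_tsv`."""
    ann = AnnotationSet(provenance={"source": str(path), "format": "tsv"})
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "gene\taspect\tterm":
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            gene, aspect, term = line.rstrip("\n").split("\t")
            ann.by_aspect[aspect].setdefault(gene, set()).add(term)
    return ann
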