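"""Seed-deterministic synthetic generators for every pipeline input.

Every input the pipeline consumes can be generated here at toy scale: OBO
ontologies (single-rooted DAGs per aspect with a mix of single- and
multi-parent terms), GAF annotation files with planted functional modules,
planted-threshold similarity tables whose delta-C scan peaks at a recorded
grid value, and block-correlated expression matrices.  Each generator
returns a ground-truth record computed independently of the analysis modules
(brute-force reachability, direct recursion), so the truth doubles as an
oracle for the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gofnet.similarity import GeneSimilarity

OBO_NAMESPACE = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}

_GAF_TAXON = "taxon:3847"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults are deliberately small: ontologies of tens of terms, tens of
    genes, three planted cliques — enough for every pipeline property to be
    exercised and checked against brute force in seconds.
    """

    seed: int = 0
    # ontology
    terms_per_aspect: dict[str, int] = field(
        default_factory=lambda: {"BP": 14, "MF": 10, "CC": 7}
    )
    multi_parent_prob: float = 0.25
    part_of_prob: float = 0.2
    # annotations
    n_genes: int = 12
    n_modules: int = 3
    terms_per_gene: tuple[int, int] = (2, 4)
    # planted network
    n_cliques: int = 3
    clique_size: int = 20
    planted_threshold: float = 0.80
    n_background_edges: int = 400
    # expression
    expression_blocks: tuple[tuple[int, float], ...] = ((15, 0.95), (15, 0.3))
    expression_samples: tuple[int, ...] = (100, 6)


# ---------------------------------------------------------------------------
# ontology

def _toy_dag(rng: np.random.Generator, aspect: str, n_terms: int, spec: FixtureSpec):
    """Terms, (child, parent, relation) edges for one single-rooted aspect DAG."""
    terms = [f"X:{aspect}{i:04d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parents = {int(rng.integers(0, i))}
        if i >= 2 and rng.random() < spec.multi_parent_prob:
            extra = int(rng.integers(0, i))
            parents.add(extra)
        for p in sorted(parents):
            relation = "part_of" if rng.random() < spec.part_of_prob else "is_a"
            edges.append((terms[i], terms[p], relation))
    return terms, edges


def _brute_force_truth(terms, edges):
    """Descendant counts and T-values by direct reachability and recursion."""
    parents: dict[str, list[str]] = {t: [] for t in terms}
    children: dict[str, list[str]] = {t: [] for t in terms}
    for child, parent, _ in edges:
        parents[child].append(parent)
        children[parent].append(child)

    def descend(t):
        seen = set()
        stack = [t]
        while stack:
            node = stack.pop()
            for c in children[node]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return len(seen) + 1

    counts = {t: descend(t) for t in terms}

    t_val: dict[str, float] = {}

    def tv(t):
        if t in t_val:
            return t_val[t]
        if not parents[t]:
            t_val[t] = 1.0
        else:
            t_val[t] = sum(
                (counts[t] / counts[p]) * tv(p) for p in parents[t]
            ) / len(parents[t])
        return t_val[t]

    for t in terms:
        tv(t)
    return counts, t_val


def make_toy_ontology(spec: FixtureSpec, path=None) -> tuple[str, dict]:
    """Generate an OBO document and its ground truth.

    Returns the OBO text and a truth dict with per-term aspect, parents,
    descendant counts and T-values (brute-force computed).  If ``path`` is
    given the text is also written there.
    """
    rng = np.random.default_rng(spec.seed)
    lines = ["format-version: 1.2", "ontology: toy", ""]
    truth = {"aspect": {}, "parents": {}, "descendant_count": {}, "t_value": {}}

    for aspect in ("BP", "MF", "CC"):
        n_terms = spec.terms_per_aspect.get(aspect, 0)
        if n_terms < 2:
            continue
        terms, edges = _toy_dag(rng, aspect, n_terms, spec)
        counts, t_vals = _brute_force_truth(terms, edges)
        parent_map: dict[str, list[tuple[str, str]]] = {t: [] for t in terms}
        for child, parent, relation in edges:
            parent_map[child].append((parent, relation))
        for term in terms:
            lines.append("[Term]")
            lines.append(f"id: {term}")
            lines.append(f"name: synthetic term {term}")
            lines.append(f"namespace: {OBO_NAMESPACE[aspect]}")
            for parent, relation in parent_map[term]:
                if relation == "is_a":
                    lines.append(f"is_a: {parent} ! synthetic term {parent}")
                else:
                    lines.append(f"relationship: part_of {parent} ! synthetic term {parent}")
            lines.append("")
            truth["aspect"][term] = aspect
            truth["parents"][term] = sorted(p for p, _ in parent_map[term])
            truth["descendant_count"][term] = counts[term]
            truth["t_value"][term] = t_vals[term]

    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text, truth


# ---------------------------------------------------------------------------
# annotations

def make_annotations(spec: FixtureSpec, ontology_truth: dict, path=None) -> tuple[str, dict]:
    """Generate a GAF 2.2 document with planted functional modules.

    Genes are split into ``n_modules`` modules; genes of the same module draw
    their terms from a shared per-module term pool, so within-module term
    overlap (hence BMA similarity) exceeds between-module overlap by
    construction.  The truth records module membership and every
    (gene, aspect, term) entry.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_aspect: dict[str, list[str]] = {"BP": [], "MF": [], "CC": []}
    for term, aspect in ontology_truth["aspect"].items():
        by_aspect[aspect].append(term)
    for terms in by_aspect.values():
        terms.sort()

    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    module_of = {g: i % spec.n_modules for i, g in enumerate(genes)}

    # per-module, per-aspect pools (disjoint between modules where possible)
    pools: dict[tuple[int, str], list[str]] = {}
    for aspect, terms in by_aspect.items():
        if not terms:
            continue
        shuffled = list(terms)
        rng.shuffle(shuffled)
        chunk = max(1, len(shuffled) // spec.n_modules)
        for mod in range(spec.n_modules):
            pool = shuffled[mod * chunk:(mod + 1) * chunk] or shuffled[:chunk]
            pools[(mod, aspect)] = sorted(pool)

    rows = []
    truth = {"module_of": module_of, "entries": []}
    lo, hi = spec.terms_per_gene
    aspect_letter = {"BP": "P", "MF": "F", "CC": "C"}
    for gene in genes:
        mod = module_of[gene]
        for aspect in ("BP", "MF", "CC"):
            pool = pools.get((mod, aspect))
            if not pool:
                continue
            k = min(len(pool), int(rng.integers(lo, hi + 1)))
            chosen = sorted(rng.choice(pool, size=k, replace=False))
            for term in chosen:
                rows.append(
                    "\t".join([
                        "SYN", gene, gene, "", term, "SYN:0000001", "IEA", "",
                        aspect_letter[aspect], f"synthetic {gene}", "", "protein",
                        _GAF_TAXON, "20240101", "SYN", "", "",
                    ])
                )
                truth["entries"].append((gene, aspect, term))

    text = "!gaf-version: 2.2\n" + "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text, truth


# ---------------------------------------------------------------------------
# planted-threshold similarity tables

def make_planted_network(spec: FixtureSpec) -> tuple[list[GeneSimilarity], dict]:
    """Similarity table whose delta-C scan peaks at a planted grid threshold.

    Cliques carry within-clique weights just above the planted threshold;
    between-clique background pairs carry weights stratified over every 0.01
    bin below it, so each grid step up to the threshold strips some
    background edges and the clustering-coefficient gap rises until the
    network is reduced to the pure cliques exactly at the planted value.
    """
    rng = np.random.default_rng(spec.seed + 2)
    t_planted = round(spec.planted_threshold, 2)
    genes = [f"N{i:03d}" for i in range(spec.n_cliques * spec.clique_size)]
    clique_of = {g: i // spec.clique_size for i, g in enumerate(genes)}

    records: list[GeneSimilarity] = []

    def add(a, b, w):
        a, b = sorted((a, b))
        records.append(GeneSimilarity(a, b, 0.0, 0.0, 0.0, round(float(w), 6)))

    # within-clique edges: weights in [t_planted + margin, 0.985]
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if clique_of[a] == clique_of[b]:
                add(a, b, rng.uniform(t_planted + 0.005, 0.985))

    # background between-clique edges: stratified over every 0.01 bin in
    # [0.01, t_planted) so each grid step below the planted value strips edges
    cross_pairs = [
        (a, b)
        for i, a in enumerate(genes)
        for b in genes[i + 1:]
        if clique_of[a] != clique_of[b]
    ]
    chosen = rng.choice(len(cross_pairs), size=min(spec.n_background_edges, len(cross_pairs)), replace=False)
    bins = np.arange(0.01, t_planted - 0.005, 0.01)
    for rank, idx in enumerate(sorted(chosen)):
        a, b = cross_pairs[idx]
        lo = bins[rank % len(bins)]
        add(a, b, rng.uniform(lo, min(lo + 0.009, t_planted - 0.003)))

    records.sort(key=lambda r: (r.gene_a, r.gene_b))
    truth = {
        "threshold": t_planted,
        "clique_of": clique_of,
        "n_cliques": spec.n_cliques,
        "clique_size": spec.clique_size,
    }
    return records, truth


# ---------------------------------------------------------------------------
# expression matrices

def make_expression(spec: FixtureSpec) -> tuple[list[pd.DataFrame], dict]:
    """Block-correlated expression matrices with known pairwise correlations.

    Each dataset holds blocks of genes following a one-factor model
    ``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` so the population correlation
    within a block is ``rho`` and zero between blocks.  Sample counts follow
    ``expression_samples``; counts below the co-expression module's default
    minimum exercise dataset dropping.
    """
    rng = np.random.default_rng(spec.seed + 3)
    datasets = []
    truth = {"datasets": []}
    for ds_index, n_samples in enumerate(spec.expression_samples):
        rows = []
        index = []
        block_of = {}
        gene_counter = 0
        for block_index, (block_size, rho) in enumerate(spec.expression_blocks):
            factor = rng.standard_normal(n_samples)
            for _ in range(block_size):
                gene = f"E{gene_counter:03d}"
                gene_counter += 1
                noise = rng.standard_normal(n_samples)
                rows.append(np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise)
                index.append(gene)
                block_of[gene] = (block_index, rho)
        df = pd.DataFrame(
            np.asarray(rows), index=index,
            columns=[f"S{ds_index}_{j}" for j in range(n_samples)],
        )
        datasets.append(df)
        truth["datasets"].append(
            {"n_samples": n_samples, "block_of": block_of}
        )
    return datasets, truth


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
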