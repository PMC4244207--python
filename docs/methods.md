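# Methods

## The model

`gofnet` treats gene function as a position in the Gene Ontology's three
rooted DAGs (biological process, molecular function, cellular component;
`is_a` and `part_of` merged as parent edges, obsolete terms and any other
relation excluded) and derives a single weighted gene network from it.

**Semantic totipotency.**  Each term carries a T-value modelling how much
"differentiation capacity" of its ancestors it retains.  Roots have T = 1;
any other term has

    T(t) = mean over parents p of [ omega(t, p) * T(p) ],
    omega(t, p) = D(t) / D(p),

where D is the self-inclusive descendant count.  omega is strictly inside
(0, 1) on every edge of a DAG (a child's descendant set is a proper subset
of its parent's), decreases down the hierarchy, and grows with the local
density of the term — the three properties the factor must satisfy.  The
ratio rule is one admissible algebraic form with those properties; it is
exposed as a pluggable strategy (`omega_fn`) so an alternative factor can be
substituted without touching the traversal.  Multi-parent terms apply omega
per parent inside the average, keeping T(child) strictly below the mean of
its parents' T-values.

**Term distance and similarity (SSDD).**  For two terms of the same aspect
the distance sums T over the term set of the shortest path joining them
through a lowest common ancestor, normalised into (0, 1):

    d(t1, t2) = (2/pi) * arctan( sum of T over the path ),   s = 1 - d.

Path selection minimises, lexicographically, (hop count, summed T, term
ids); the deterministic tie-break makes paths exactly reversible, so the
similarity is symmetric by construction.  The bare arctan would range up to
pi/2, hence the 2/pi factor.  Under the literal path rule an identical pair
has path {t}, so self-similarity is below 1 (exactly 0.5 at a root); because
the self-case is a convention rather than a consequence of the model, a
switch (`identical_term_sim_one`) forces s(t, t) = 1 for users who prefer
the fixed-point convention.  The literal rule is the default.  Cross-aspect
pairs are defined as similarity 0 and flagged.

**Gene similarity.**  Per aspect, the best-match average over the two genes'
term sets:

    BMA(A, B) = 1/2 * [ mean_a max_b s(a, b) + mean_b max_a s(a, b) ].

A gene unannotated in an aspect contributes aspect similarity 0 — not an
error — and the integration

    s_INT = (s_BP^2 + s_MF^2 + s_CC^2) / (s_BP + s_MF + s_CC)

is a self-weighted average: it always lies between the minimum and maximum
of the nonzero inputs, so a zero aspect dilutes but cannot destroy the
integrated similarity.  The integrated gene universe is the union of genes
annotated in any aspect; per-aspect networks use per-aspect universes.
All-pairs tables stream in sorted order with a term-pair similarity cache,
so files are deterministic and memory stays bounded by the cache, not the
pair count.

## Threshold selection

Edges keep every pair with similarity >= t (zero-similarity pairs are never
edges; genes left isolated are dropped, so node counts shrink with t).  On
the grid t = 0.00, 0.01, ..., 1.00 the scan records

    delta(t) = C_obs(t) - C_rand(t),

with C_obs the mean node clustering coefficient (0 for degree < 2; 0 for an
empty network) and C_rand the configuration-model expectation
(⟨k²⟩−⟨k⟩)² / (N⟨k⟩³) evaluated on the realized degree sequence.  The
selected threshold is the smallest t >= 0.01 with delta(t) >= delta(t+0.01):
the first stop — peak or plateau — of delta's increasing run.  If delta
still rises at the grid end, 1.00 is returned with an explicit flag rather
than silently.  Starting the comparison at 0.01 (not 0.00) makes the
degenerate monotone-decreasing case resolve to the first real grid step.

C_rand's closed form is an approximation (exact only asymptotically for
configuration-model graphs); on Erdős–Rényi graphs it sits within a few
percent of sampled clustering, which the tests check against a Monte-Carlo
sample rather than a point value.  It too is replaceable as a strategy.

## Topology

Degree distributions are relative frequencies at raw observed degrees, no
binning.  Three models are fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), each initialised from a log-linear pre-fit:

- lognormal: y = y0 + A/(sqrt(2 pi) sigma x) exp(-(ln x - mu)^2 / 2 sigma^2)
- power law: y = a x^b
- exponential: y = y0 + A e^(b x)

with sigma > 0 and amplitudes >= 0.  Non-convergence returns a flagged fit
(never an exception) and the best model is the highest R^2 among converged
fits.  At least 5 distinct degrees are required.  Degree correlations:
joint degree distribution over unordered endpoint-degree pairs (sums to
|E|), mean neighbour degree per degree class (absent degrees skipped), and
the Pearson correlation of endpoint degrees with both orientations per edge
(standard assortativity).  A constant endpoint-degree sequence makes the
correlation undefined; the package reports 0 with a warning.

## Validation

Reference networks: clique expansion of shared pathway terms; co-expression
with edges at |PCC| strictly above 0.8 per dataset (datasets under 20
samples discarded, constant-expression genes skipped), unioned across
datasets; orthology transfer of source-species edges through a one-to-many
ortholog map with collapsed self-pairs dropped.  The uninformative-dataset
correlation pre-filter sometimes applied upstream of co-expression networks
is under-specified and deliberately omitted: dataset filtering is by sample
count only.

Gene coverage Cg = 100 * Ns / Nk (shared genes over reference genes).  For
linkage accuracy the default takes the query's edges among shared genes as
the denominator and those confirmed by the reference as the numerator, so
La <= 100 always; the variant that divides the query's shared-gene edge
count by the reference's (which can exceed 100) is available via
`literal_la=True`.  Percentages are reported to 2 decimals.

Significance uses the query's own degree sequence as the null: 400
randomized replicas by accepted double-edge swaps (10 per edge, rejecting
loops and multi-edges), La recomputed per replica, and a one-sided add-one
empirical p — rank of the observed La in the background sample.  With 400
replicas the smallest attainable p is 1/401 ≈ 0.0025.  A one-way ANOVA
helper is provided for comparing several query networks' background
samples.

## Prediction

Candidates are direct neighbours of the query genes (never queries
themselves); the analysis module is the largest connected component of the
induced query+candidate subgraph.  Each candidate's WR score shrinks its
mean edge weight to adjacent queries (F) toward the cross-candidate mean
(C) by its query-neighbour count v against the prior m, the first quartile
(linear-interpolation) of the candidates' v distribution:

    WR = v/(v+m) * F + m/(v+m) * C.

F averages edges to queries only (not to all known genes in the module); a
flagged alternative could widen this, but queries-only is the implemented
rule.  Ties in WR rank lexicographically by gene id, making rankings
deterministic.  A one-step weight-normalised label-diffusion smoother is
included as a clearly-labelled extension; the direct-neighbour rule is the
primary discovery route.

## Synthetic data

The generators in `gofnet.fixtures` define the study conditions at toy
scale and record ground truth computed independently of the analysis code
(brute-force reachability and direct recursion), so the truth files double
as oracles:

- **Ontologies**: per-aspect single-rooted DAGs (defaults 14/10/7 terms for
  BP/MF/CC), 25% multi-parent terms, 20% part_of edges.
- **Annotations**: 12 genes in 3 modules, 2–4 terms per gene per aspect
  drawn from disjoint per-module term pools, so within-module similarity
  exceeds between-module similarity by construction.
- **Planted-threshold tables**: 3 cliques of 20 genes with internal weights
  just above the planted cutoff (default 0.80) and ~400 between-clique
  background pairs whose weights are stratified over every 0.01 bin below
  it; each grid step below the cutoff therefore strips some background
  edges and delta rises monotonically to a peak exactly at the planted
  value.
- **Expression**: one-factor blocks x = sqrt(rho) f + sqrt(1-rho) eps, so
  within-block correlation is rho and between-block zero; sample counts
  (100, 6) exercise the minimum-sample rule.

What the fixtures do *not* emulate: realistic GO term depth (tens of
thousands of terms, 10+ levels), evidence-code composition, annotation
bias toward well-studied genes, heavy-tailed degree sequences at genome
scale, or expression noise structure beyond Gaussian one-factor blocks.
Passing tests therefore demonstrate the correctness of the algorithms and
their bookkeeping, not the biological performance of the method on a real
genome.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small sizes — DAGs of
up to 30 terms, gene sets of tens, networks of up to 200 nodes, 20 planted
fixtures, 400 rewiring replicas — chosen so every quantity can be
cross-checked against exhaustive enumeration in seconds.  Floating-point
comparisons in tests use exact equality only where the computation is
identical arithmetic, and relative tolerances elsewhere.  Degenerate inputs
are conventions, not errors, wherever the field treats them so: empty term
set → aspect similarity 0; empty network → clustering 0; regular graph →
assortativity 0 with flag; k < 2 → node clustering 0.

## Known limitations

- The omega ratio rule and the (2/pi) arctan normalisation are admissible
  concrete forms of constraints that admit alternatives; both are pluggable.
- The configuration-model C_rand is approximate for dense or very small
  graphs (it can exceed 1 on cliques).
- All-pairs similarity is quadratic in gene count; genome-scale runs need
  the streaming writer and hours of CPU, not this package's test settings.
- The empirical background p is bounded below by 1/(n_random+1).
- Annotation propagation to ancestors is intentionally not performed; the
  path-based similarity operates on the DAG directly.
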