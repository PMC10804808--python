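# Methods

This note documents the models and procedures coexkit implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Coexpression model

Coexpression is measured by the Pearson correlation coefficient (PCC)
between two genes' TPM profiles across samples. The correlation is defined
directly on TPM; an optional `log_transform` flag applies log2(TPM + 1)
first. At least 3 samples are required (with fewer, the correlation is
either undefined or trivially ±1), missing values are not supported
(impute upstream if needed), and genes with zero variance across samples
yield *undefined* correlations — they are masked, never coerced to 0.

Raw correlation alone is a poor edge criterion in large matrices: a hub
gene can be the 500th-best partner of thousands of genes while still
exceeding any fixed PCC cut. The mutual rank MR(AB) = √(Rank(AB)·Rank(BA))
measures reciprocity instead: Rank(AB) is B's position in A's partner list
sorted by PCC, and the geometric mean is small only when each gene ranks
the other highly. Consequences of the definition that the code and tests
rely on:

- MR is symmetric by construction and lies in [1, G−1] for G genes;
  MR = 1 iff the two genes are mutually each other's best partner.
- MR is bracketed by min and max of the two directional ranks
  (geometric-mean inequality).
- Ranks depend only on the *order* of correlations, so any monotone
  rescaling of the correlation values leaves the rank structure unchanged.

**Rank directions.** Ranks are computed separately with partners sorted by
descending PCC (positive side) and ascending PCC (negative side). A single
descending ranking would give strongly anti-correlated pairs the *worst*
ranks, making any "MR below a cut" criterion unsatisfiable for the negative
network; the ascending direction restores symmetry between the two sides.

**Ties.** Equal correlations are ranked in lexicographic partner-id order.
This is arbitrary but deterministic, and it makes every output
bit-reproducible — which the test suite asserts.

## Threshold calibration

The operating point is selected by a co-annotation benchmark:

1. **Prior gene sets.** Annotation terms (e.g. GO biological process) are
   intersected with the expressed genes and kept when the intersected size
   falls in [4, 20] (`PriorSetConfig`; an `intersect_first=False` mode
   filters on the raw size instead). Small terms carry the most specific
   functional signal; large terms dilute the benchmark.
2. **Pair labels.** The instance universe is every unordered pair of genes
   annotated to at least one prior term; a pair is positive iff it shares a
   term. Both classes must be non-empty or the AUC is undefined (error).
3. **Grid scoring.** For each candidate cell (PCC cut, MR cut) — defaults
   0.6/0.7/0.8/0.9 on the positive side, −0.4/−0.5/−0.6/−0.7 on the
   negative side, MR 10/25/50/100 — a pair passing the cuts (PCC beyond the
   threshold on its side *and* MR strictly below the cut, using the
   side-matched rank direction) scores |PCC|; all other pairs score 0. The
   AUC of that score against the labels is the Mann–Whitney statistic with
   ties counted one half.
4. **Selection.** The maximal-AUC cell wins; among cells within
   `tie_epsilon` (default 0.01) of the maximum, the loosest cell (smallest
   |PCC| cut, then largest MR cut) is preferred, encoding an explicit
   inclusiveness preference: when the benchmark cannot distinguish cells,
   keep more genes.

The calibration benchmark is deliberately defined on thresholded scores
rather than raw |PCC|: it evaluates the *network construction rule*, not
the correlation measure. The module contains no randomness; permutation
nulls in the tests shuffle labels outside of it.

Default MR candidates and `tie_epsilon` are package choices exposed as
parameters; there is no canonical value for either, and calibration
results always record the grid and epsilon actually used.

## Network assembly

At an operating point (defaults: PCC > 0.6 with MR < 50 positive,
PCC < −0.5 with MR < 50 negative — all inequalities strict, tested at the
boundary), the signed network is the union of:

- thresholded edges (origin `threshold`), and
- each gene's `top_k` (default 3) highest-PCC partners (origin `topk`, or
  `both` when the edge also passes thresholds).

Top-k retention is *guaranteed inclusion*, not a cap: it keeps every gene
connected to its best partners even when no pair passes the global cuts,
at the price of admitting weak edges around isolated genes. A `cap` mode
(restrict the positive network to edges in some endpoint's top-k list) is
available for users who want sparsification instead. Retention applies to
the positive side; an edge whose retained partner is actually negatively
correlated keeps the sign of its PCC, since edge sign always follows the
sign of the correlation. Edges are deduplicated on lexicographically
sorted endpoints; self-loops cannot arise.

Because all comparisons are strict and top-k is a union, loosening any
threshold (with `top_k=0`) can only add edges — a monotonicity property the
suite verifies over a threshold grid — and with `top_k=0`, `mr_cut=∞` the
construction reduces to plain PCC thresholding.

**PPI projection.** Reference protein–protein interactions are transferred
through an ortholog map as interologs: edge (s1, s2) projects to every
(t1, t2) with s1→t1, s2→t2, dropping self-loops and duplicates. The map may
be many-to-many; source edges with no projection are counted and reported.
Projected edges carry no confidence score — none is defined by the inputs.

**DEG overlay.** Each contrast writes its own independent node attribute
(up/down/none); topology never changes; exports carry the conventional
color hints (red = up, #FF0000; blue = down, #0000FF). DEG genes absent
from the network are ignored and counted.

## Enrichment

**ORA** uses the upper-tail hypergeometric test P(X ≥ k) for an overlap of
k between an n-gene query and a K-gene term in an N-gene universe
(scipy's survival function; the tests check it against exact
binomial-coefficient summation to 1e−12 on all universes up to N = 25),
with Benjamini–Hochberg FDR across the tested terms. The default universe
is the full expression matrix; restricting to annotated genes is the
caller's choice of `universe`. Query genes outside the universe are
dropped, not fatal.

**Preranked GSEA** uses the classic weighted running-sum statistic: walking
the score-ordered list, term members add |score|^weight normalised over the
term's members (weight 1 by default; weight 0 recovers the unweighted
Kolmogorov–Smirnov form, which the tests check against an independent
implementation), non-members subtract 1/(N−K); the enrichment score is the
maximum signed deviation, bounded by [−1, 1]. Significance comes from
gene-label permutations — random same-size gene sets drawn from the list —
because a preranked list has no sample-level phenotypes to permute. The
estimator p = (count + 1)/(n_permutations + 1) is two-sided on |ES| and
cannot return zero. All permutations flow from one seeded generator.

## Synthetic data

The generator plants known structure so recovery is measurable exactly.
Log-expression of gene g in sample s is

    b_g + polarity_g · z_m(s) + ε,   z_m ~ N(0, signal_sd²), ε ~ N(0, noise_sd²)

with per-gene baseline b_g ~ N(2, 1), polarity −1 for anti-correlated
module members, and background genes receiving baseline plus noise only;
TPM = exp(·). Defaults — 10 modules × 8 genes, 40 background genes,
30 samples, signal_sd 1.0, noise_sd 0.3 — describe a small, well-powered
study: at these settings the within-module log-scale correlation is
signal²/(signal² + noise²) ≈ 0.92 in expectation, comfortably above the
0.6 operating point but close enough that noise matters. Anti-correlated
members are opt-in (`n_anticorrelated_per_module`, default 0): they model
repressed members of a process, and planting them also plants
anti-correlated *term pairs*, which by construction caps the positive-side
co-annotation AUC below 1 (an opposite-polarity pair shares a term but can
never pass a positive-PCC cut). The calibration benchmark is therefore run
on the default conditions, and negative-network recovery on a companion
run with 2 anti-correlated members per module.

Ground truth exposes module assignment, polarity, the planted pair lists,
and a term collection with one term per module covering all its members —
the synthetic analogue of functional annotation.

**Why analyses of synthetic data use log2(TPM+1).** The planted structure
is log-additive, and exponentiation attenuates correlations asymmetrically:
for jointly log-normal pairs the TPM-scale correlation is
(e^{ρσ²} − 1)/(e^{σ²} − 1), which for a planted log-scale ρ = −1 at these
variances can never drop below about −0.55 — no negative threshold of
practical interest is reachable on raw TPM. The tests and the acceptance
script therefore correlate log2(TPM+1) (the documented flag); raw TPM
remains the library default for real data, matching the definition of the
statistic.

What the generator does *not* emulate: read-count noise, library-size and
length biases, sample correlation structure (batches, time courses),
annotation incompleteness, and overlapping modules. Passing the recovery
tests shows the pipeline's logic is correct under the stated generative
model, not that real networks at these thresholds have these error rates.

**False-positive accounting.** The background false-positive rate reported
by the benchmark counts threshold-passing edges between background genes
(origin `threshold`/`both`) over all background pairs. Top-k retention
edges are excluded from the numerator: they are threshold-independent
guaranteed inclusions, present by design for every gene regardless of
evidence, so counting them would measure the retention policy rather than
the thresholding.

## Numerical choices

- Correlations are computed by the one-pass normalised-dot-product route,
  symmetrised exactly ((C + Cᵀ)/2) and clipped to [−1, 1] only to absorb
  rounding at the 1e−12 level; agreement with a two-pass textbook oracle is
  asserted to 1e−10.
- Floats are serialised with `repr` (shortest round-trip form), so
  write-then-read is the identity and reruns are byte-identical.
- Problem sizes throughout the test suite and the acceptance script
  (120–140 genes, 30 samples, ≤ 1000 permutations) are chosen so the full
  pipeline runs in seconds while every planted-structure statistic is
  far from its decision boundary.

## Known limitations

- Dense G×G correlation and rank matrices: memory is O(G²), fine to a few
  tens of thousands of genes on a workstation but not beyond; the dense
  result is the semantic contract, so any blocked implementation must
  reproduce it exactly.
- Only Pearson correlation is offered (no Spearman/biweight), and only
  pairwise edges (no module detection or clustering).
- The calibration benchmark inherits the biases of the annotation it is
  fed; terms outside the 4–20 size window contribute nothing.
- GSEA reports ES and permutation p only (no normalised ES across terms,
  no leading-edge extraction).
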