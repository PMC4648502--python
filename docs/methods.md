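# Methods

## Model and assumptions

`sigpca` treats a genes × samples expression matrix (log-scale, continuous)
as observations of correlated gene programs superimposed on noise. It makes
no distributional assumption about the expression values themselves: both
of its statistical engines are nonparametric. PCA is used purely as a
device to order genes — each component's loadings rank genes by how
strongly they co-vary along that axis — and the XL-mHG test asks whether a
gene set is concentrated at the top of such a ranking, conditioning only on
the ranking, not on the values. The implicit assumptions are that
biologically coherent programs dominate the leading principal components,
and that the annotation source (ontology-derived or custom gene sets)
contains a set that describes each program.

## Gene-set preparation

Annotations are read from a GAF 2.x file, keeping only manually curated
evidence codes (IDA, IGI, IMP, ISO, ISS, IC, NAS, TAS) and dropping
negated (`NOT`) rows, then propagated up the ontology: a gene annotated
with a term is annotated with every `is_a` ancestor, and for
cellular-component terms `part_of` edges are traversed identically
(a part's presence implies the whole's). Sets outside a 5–200 gene window
are removed — smaller sets cannot satisfy the X constraint stably, larger
ones make uninformative labels. Finally, a parent whose propagated set is
identical to a *direct* child's is removed (the child is the more specific
label); equality is compared per edge, so identity propagates up a chain
exactly when every intermediate matches. Gene identity is the symbol
column, matched case-sensitively against expression row labels.

## The XL-mHG test

For a ranked binary list v ∈ {0,1}^N with K ones, the statistic is

  s^mHG = min over testable n of P(Hypergeom(N, K, n) ≥ k(n)),

where k(n) counts ones among the first n entries and n is *testable* iff
n ≤ L and k(n) ≥ X. If no cutoff is testable, s = 1 with attaining cutoff
0 — never an error, so a downstream significance screen simply fails.
Ties are broken toward the smallest attaining n, making the reported
driving-gene set (annotated genes at or above n*, 1-based, inclusive)
minimal.

The exact p-value P(statistic ≤ s) under a uniform random arrangement is
computed by a forward dynamic program over the lattice of (prefix length,
ones seen) states: the recursion tracks the probability of reaching each
state without having entered the rejection region {(n, k): n testable,
tail(k; N, K, n) ≤ s}, and p = 1 − surviving mass. This is O(NK) time,
O(K) space, and works entirely in probability space, so every intermediate
lies in [0, 1].

Numerical choices:

* The region membership test uses the same tail function as the statistic
  (scipy's hypergeometric survival function) with a relative slack of
  1e-12, so statistic and region classification can never disagree on the
  attaining cell.
* s = 1 (to within the same slack) returns p = 1 directly: every
  arrangement attains a statistic ≤ 1, including the degenerate
  no-testable-cutoff case which attains exactly 1.
* Because p is obtained as 1 − survival, p-values below ~2.2e-16 are
  reported at the floating-point cancellation floor rather than their true
  magnitude. This never affects significance decisions (the threshold is
  1e-6) and the statistic s, which is computed directly, retains full
  dynamic range for effect ranking.
* p is clamped to max(p, s), preserving the analytic bound s ≤ p under
  floating point.

The implementation is verified against an exhaustive enumeration oracle
(every arrangement of K ones in N slots, C(N,K) ≤ 200,000) at every support
point of the statistic's distribution for all N ≤ 12, all K, X ∈ {1,2,3},
L ∈ {⌈N/2⌉, N}; agreement is exact to 1e-12 relative.

## Number of components

Permuting each gene's values independently destroys inter-gene correlation
while preserving marginals. The fraction of variance explained by the
*first* component of a permuted matrix, collected over `n_perm = 15`
permutations, gives a null mean and sample sd; real components are
z-scored against it and D is the length of the initial run with
z ≥ 2.0. Using the first permuted component as the reference for *all*
real components is deliberately conservative for later components. Genes
are centered but not rescaled before PCA by default (`pca_scale` enables
unit-variance rescaling); standardization enters only in signature
construction. All standard deviations use the n−1 denominator.

## Filters and signature construction

Within one ranking, the local filter visits significant sets by decreasing
fold enrichment (k\*/n\*)/(K/N) — the only effect size computable from the
quantities the test defines, used here as the enrichment score — breaking
ties by smaller p, then term id. Each set is re-tested on the ranking with
all previously accepted sets' driving genes deleted (the list contracts;
K is recomputed; the set's original X is kept and L is clipped to the
shrunken length) and dropped if p > α_B.

Across components (|pc| ascending, positive ranking before negative), a
set related to any previously kept set — transitive ancestors and
descendants; a flag restricts this to direct neighbors — is suppressed.
Suppression applies between the two rankings of the same component as
well, so the final output is always pairwise unrelated; earlier components
are prioritized because they explain more variance.

Signature construction: seed = mean standardized profile of the X driving
genes most correlated with the driving-genes' average profile (all of them
if there are at most X); remaining driving genes join iff their Pearson
correlation with the seed is ≥ R (default 0.5; R = −1 disables the
filter). The seed's candidates are restricted to driving genes, keeping
labels annotation-faithful; the signature profile is the unweighted mean of
member z-scores and therefore has zero mean across samples. Display order
is the dendrogram leaf order of average-linkage clustering on correlation
distance (1 − r) between signature profiles.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `x_frac` | 0.25 | minimal fraction of a set's genes above a tested cutoff |
| `x_min` | 5 | absolute floor for X |
| `l_rank` | ⌊N/8⌋ | deepest tested rank (N/8 reflects the two-sided use of each PC) |
| `alpha_b` | 1e-6 | fixed per-test threshold (≈ 0.05 Bonferroni over the ~20,000 tests per PC a full ontology implies, rounded down) |
| `r_corr` | 0.5 | seed-correlation threshold for signature membership |
| `z_threshold` | 2.0 | permutation-test z cutoff for keeping a component |
| `n_perm` | 15 | permutations for the component-count null |
| `top_n_variance` | off | restrict to the most variable genes (recommended on real data to exclude unexpressed genes) |

`alpha_b` is intentionally *not* divided by the number of components
tested; this keeps the signatures of the leading components invariant when
the analysis is re-run with a different D (verified by test).

## Bootstrap robustness

B (default 50) resamples of the samples, with replacement, optionally at
several fractions of the original size; the pipeline is re-run with
identical parameters, each replicate seeded as root seed + replicate index
so any single replicate is independently reproducible. A signature is
detected in a replicate if its exact term — or, in related mode, any
ancestor/descendant — generated a signature there, regardless of which
component produced it; component identity is analysed separately by the
PC-prefix detection matrix, whose rows are non-decreasing in the window
width by construction.

## The synthetic generator

`make_dataset` emulates the target structure: i.i.d. Gaussian background
(sd 1), disjoint gene modules additively shifted by a chosen effect (in sd
units, on the log scale where the pipeline operates) in a random sample
subset, matching one-term-per-module annotations, optional annotation
contamination, decoy sets of random genes, and an optional toy ontology
parent per planted term. It does not simulate platform-specific technical
noise (probe effects, library-size variation, dropout), mean–variance
coupling, or overlapping/nested modules; passing tests therefore
demonstrate correctness of the algorithmic chain and its calibration under
the stated model, not robustness to every artifact of real data.

Default study conditions used by the tests and the acceptance script:
1000 genes × 60 samples, three 40-gene modules with effect 3 sd active in
30% of samples, 500 decoy sets of 5–50 genes. Null calibration uses
200 × 30 noise matrices; the exhaustive oracle sweep uses N ≤ 12. These
sizes were chosen once as representative desk-scale instances of the
method's regime.

## Known limitations

* Exact p-values saturate at ~2.2e-16 (see above); ranking below that
  level relies on the statistic s.
* The local filter's greedy order depends on the enrichment score; a
  different score definition (the hook is configurable) changes which of
  two overlapping sets survives.
* The component-count test assumes exchangeable samples; strong batch
  structure will register as real components.
* Single-threaded by design — determinism is prioritized over speed; a
  full ontology run on ~10,000 sets and thousands of genes takes minutes,
  not seconds.
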