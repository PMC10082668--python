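# Methods

## The model

`flexms` treats a microbiome sample as a relative-abundance measure over
the leaves of a shared rooted phylogeny.  Two samples are compared by the
mass they can match on that tree, with matching across different leaves
penalized by the branch lengths separating them.

**Consistency recursion.**  For leaf *sp* with abundances S1 and S2 in the
two samples, the matched mass is Con(*sp*) = min(S1, S2); the surplus of
the larger sample survives as a one-sided residual.  At an internal node,
each child's residuals are first attenuated by max(0, 1 − *d*) where *d*
is the child's branch length (branch lengths are substitution distances;
*d* ≥ 1 blocks matching entirely), then surpluses belonging to *opposite*
samples are matched and added to the accumulated consistency; surviving
residuals propagate upward.  Multifurcations are resolved pairwise
left-to-right through zero-length virtual edges, which is equivalent to an
arbitrary binary resolution because residuals are one-sided after every
combine (pooling all children at once gives the same result — the property
the independent test oracle exploits).  The recursion is greedy and
bottom-up, not an optimal transport: mass is always matched at the lowest
node possible.

**Distance.**  Both input vectors are renormalized to sum 1 before the
recursion, so Con(root) ∈ [0, 1] and

Dist(S1, S2) = 1 − Con(root).

An alternative normalization — 2·(1 − Con)/(ΣS1 + ΣS2) on raw
restricted abundances — does not vanish for identical samples; the
per-sample renormalization makes that denominator identically 2, restores
Dist(a, a) = 0, and keeps the distance scale-free.  Identical samples give
0; samples whose restricted supports are disjoint and phylogenetically
saturated give 1.  If a sample carries no mass at all on the target set,
nothing can be matched and its distance to everything is reported as 1
(with a log warning) — absent evidence is treated as maximal
dissimilarity.

**Local vs. global.**  The local (FMS) distance runs the recursion on the
target member set T only; the global Meta-Storms baseline is the identical
recursion with T = all features at weight 1, so the two are algebraically
the same operator and exactly equal when T covers every feature (a test
asserts bit-equality).

## Target member set

Exact markers come from a two-sided Wilcoxon rank-sum test (two groups;
normal approximation with tie correction) or Kruskal–Wallis (three or
more), selected at *p* < α with α = 0.01 and **no** multiple-testing
correction — the selection is deliberately plain so the distance, not the
marker picker, carries the method; a Benjamini–Hochberg flag exists but is
off by default.  Marker lists can also be supplied verbatim.

Approximate markers are read from the neighbor index:
AN(*i*) = PN(*i*) ∩ FN(*i*), where PN requires sequence identity
≥ *t*<sub>s</sub> *and* an identical full lineage string, and FN requires
functional distance ≤ *d*<sub>f</sub>.  Both boundaries are inclusive, as
the definitions state.  An approximate member indexed from several exact
markers takes the *maximum* similarity as its weight (its nearest exact
marker); a feature that is itself exact keeps weight 1 even if it is also
someone's neighbor — its own abundance is already evidence, and
down-weighting it would discard signal.

The default thresholds *t*<sub>s</sub> = 0.92 and *d*<sub>f</sub> = 0.11
are the values derived from the Greengenes v13-8 reference build.  For any
candidate pool they can be re-derived with the top-0.1% percentile rule:
*t*<sub>s</sub> is the k-th largest pooled pairwise similarity with
k = ⌊qN⌋ (q = 0.001), i.e. the top q fraction of pairs lie at or above it.
*d*<sub>f</sub> mirrors the rule on the low tail of the functional
distances; q is exposed as a parameter.  With fewer than
1/q values the rule degenerates to the extreme value, with a warning.

**Sequence identity** is a Needleman–Wunsch global-alignment identity with
match = 1, mismatch = 0, gap = 0: the DP maximizes matches, breaking score
ties toward the fewest gaps, and identity = matches / alignment columns.
This is parameter-free and deterministic; parity with VSEARCH's heuristics
is not promised.

**Functional distance** is a level-weighted Bray–Curtis over the KO
hierarchy: each profile is renormalized to sum 1, aggregated at the KO,
pathway (level-2) and super-category (level-1) strata, and the per-level
Bray–Curtis values are combined with weights (⅓, ⅓, ⅓) by default.  This definition is a
proper [0, 1] dissimilarity that is 0 iff the profiles agree at every
level and 1 for categorically disjoint profiles; alternative hierarchical
functional distances can be substituted via the `level_weights` argument.  KOs missing from the hierarchy are mapped
to an "unclassified" bucket per level, with a warning.

## Numerical choices

* Residual/consistency values below 1e-12 are flushed to zero so results
  do not depend on summation order; the pairwise engine is a single
  vectorized pass over tree nodes evaluating all sample pairs at once and
  is bit-identical to the scalar recursion and for any `threads` value.
* The restricted profile matrix is sorted by feature ID before
  renormalization so the result does not depend on how T was enumerated.
* Neighbor lists are canonically ordered (descending similarity, then
  lexicographic ID); index files and target-set dumps are reproducible.
* Distance matrices are written with 6 decimals; round-trips are stable to
  1e-6.

## Evaluation battery

PCoA, PERMANOVA (Anderson's pseudo-F), ANOSIM (Clarke's R) and PERMDISP
(centroid variant, all PCoA axes) are delegated to scikit-bio with an
explicit seed; 999 permutations and a significance threshold of 0.01 are
the defaults throughout.  PERMANOVA's R² is recovered from the pseudo-F
closed form R² = F(k−1)/(F(k−1)+N−k), which a test verifies against direct
sums of squared distances.  An all-equal ("degenerate") distance matrix is
reported as statistic 0, p = 1 — no structure is claimable from it.

KNN leave-one-out classification scores each sample by the fraction of
positive labels among its k nearest other samples (k = 3 by default — odd
and small-sample friendly).  Ties at the k-th distance break by sample order, so scores are
deterministic; a distance-weighted variant is available behind a flag.
AUC follows the Mann–Whitney identity with half credit for ties.

## The synthetic scenario

`ScenarioConfig` defaults encode the artificial-experiment conditions: two
groups of 50 samples over 40 shared abundant background taxa, plus 4
planted low-abundance markers (mean 0.5% each, lognormal σ = 0.4,
per-sample presence 0.9) enriched in group A.  Each marker has a cherry
relative on the tree (leaf edges (1 − s)/2 for a drawn similarity
s ∈ [0.93, 0.98], matching taxonomy and near-identical KO profile, listed
in the generated index).  In group B, half of the markers
(`relative_presence` = 0.5, a deterministic fraction — the mixed pattern
of the motivating example; an all-replaced or none-replaced realization
would be invisible to any composition-based distance after
renormalization) are absent with their relative carrying comparable mass,
and the rest are depleted 5-fold but still observed.  Background
compositions are Dirichlet draws around one shared lognormal
rank-abundance profile with concentration 50, so the groups are
exchangeable on ~98% of their mass.

What this emulates: dilution of a real low-abundance signal below the
sensitivity of whole-community distances, and profiling sparsity that
scatters a lineage's mass across near-identical reference features.  What
it does not emulate: realistic 16S read noise, compositional correlation
structure among background taxa, copy-number effects, or the parameters of any
particular real cohort.  Passing tests therefore show the pipeline's behavior under
the documented generative recipe, not performance on any real cohort.
Under this recipe the rank test usually selects the replaced relatives as
markers too (they are group-B-enriched), so the exact-only and FMS modes
coincide on synthetic defaults; their divergence on real data comes from
markers whose relatives are *not* individually significant.

Null calibration uses the `n_markers = 0` configuration, where the groups
are exchangeable by construction.  Because re-testing group structure on a
distance built from markers selected on the same labels is circular
(selection bias, not distance behavior), the null-scenario check supplies
a label-blind random marker list to the local modes; the permutation tests
are then exactly calibrated for any fixed distance, which is what the
check certifies.

## Problem sizes

Test and reproduction runs use 20 realizations of the 100-sample scenario
for the AUC comparison, 500 null simulations (n = 10/10) for permutation-
test calibration, 50 realizations for marker-recovery rates, and 100 null
realizations for the false-structure check.  The pairwise engine computes
a 100-sample global matrix (48 leaves) in ~10 ms, so the whole battery
runs in a couple of minutes on one CPU.

## Known limitations

* The greedy recursion is not a metric in the strict sense (the triangle
  inequality is not guaranteed), like other consistency-score
  dissimilarities; PCoA on its matrices can produce negative eigenvalues,
  which are reported and excluded from coordinates.
* The internal-node rule accumulates child consistencies and matches only
  opposite-sample surpluses; simpler variants that match attenuated
  residuals without accumulating child consistency fail the basic
  requirement Dist(a, a) = 0, which is why this reading is implemented.
* Building an index from sequences is all-vs-all O(n²·L²) and intended
  for desk-scale pools; Greengenes-scale indexes should be precomputed
  once and loaded from file.
* Marker-restricted distances inherit the selection's instability at
  small n; with a single target member every sample collapses to the same
  point (all distances 0).
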