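# Methods

## The test

`rftest` is a community-level (global) association test for microbiome
data: given an abundance table **X** (n samples × p OTUs/ASVs), an
outcome **y** (binary or continuous), an optional covariate matrix
**Z**, and an optional rooted phylogeny over the taxa, it tests the
single null hypothesis that the community is independent of the outcome
(given the covariates).

The test statistic is the out-of-bag (OOB) generalization error of a
random forest fit with **y** as the response and the augmented feature
matrix **[X | W]** as predictors. For a binary outcome the forest makes
probabilistic predictions and the OOB error is the Brier score,

    T = mean_i (p_i − y_i)²,

where p_i is sample i's OOB probability of class 1 (averaged over the
trees whose bootstrap sample excluded i); for a continuous outcome it
is the OOB mean squared error. The statistic is averaged over a small
number of independently seeded forests (default 3) because the
forest's own sampling noise would otherwise widen the permutation null.

Significance comes from permutation. B replicate outcomes ỹ¹ … ỹᴮ are
generated under the null, the statistic T̃_b is recomputed for each
(same features, same forest configuration, fresh forest seeds), and

    p = (#{b : T̃_b ≤ T} + 1) / (B + 1).

Small observed error is evidence of association, so replicates *at or
below* the observed value count against significance being small; ties
count via ≤, which keeps the test valid (never anti-conservative from
ties). The attainable range is [1/(B+1), 1].

The only assumption is the one underlying any permutation test:
exchangeability of the outcome across samples under the null (after
covariate adjustment, exchangeability of the adjusted outcome).
Nothing is assumed about the abundance distribution, the link between
abundances and outcome, or taxon–taxon interactions — the forest
adapts to non-linear and interaction structure on its own.

## Phylogenetic feature augmentation

Association signals in microbiome data tend to cluster on the
phylogeny: related taxa respond similarly. To expose such signals, each
internal node l of the rooted tree contributes a feature

    w_il = Σ_{j ∈ A(l)} x_ij,

the summed abundance of its descendant leaf set A(l), computed for all
m internal nodes (root included) in one postorder pass. A clade that
shifts coherently between outcome groups appears as a single strong
column in **W** even when every member taxon is individually too noisy
to split on.

Practical details:

* Tree and table are aligned first: the tree is pruned to the shared
  taxa, internal nodes left with one child are suppressed (their
  feature would exactly duplicate the child's), and surviving nodes
  keep their identifiers, so accumulated values over surviving
  descendant sets are unchanged by pruning.
* Unlabeled internal nodes get deterministic preorder identifiers
  (`node0` = root), so the column order of **W** is reproducible.
* The root column is computed like any other and is constant for
  rarefied data; a zero-variance screen applied with the sparsity
  filter removes it (and any other constant column) transparently.
* Sparsity filter: a feature that is exactly zero in more than
  `max_sparsity` of samples is dropped (default 0.96, i.e. features
  present in fewer than 4% of samples are removed — mild filtering,
  which mostly buys speed at equal power). `max_sparsity = 1` disables
  filtering.
* Branch lengths are parsed but never used; the statistic is purely
  topological. Distance-based weighting is out of scope.

## Covariate adjustment

With covariates the null being tested is conditional independence, and
plain permutation of **y** would be wrong. Two schemes are used:

**Continuous outcome — residual permutation.** **y** is regressed on
**Z** by OLS (intercept included). The observed statistic is computed
on the *residuals* (the adjusted outcome), and each replicate outcome
is a uniformly random permutation of that residual vector, so observed
and replicate fits see identical outcome distributions.

**Binary outcome — conditional regeneration.** **y** is regressed on
**Z** by logistic regression, giving fitted probabilities π_i. Each
replicate is drawn as independent Bernoulli(π_i) *conditioned on the
total number of cases equalling the observed count*. The observed
statistic uses the raw **y**; only the null replicates are
regenerated. Conditioning removes the extra variability of the case
count and anchors the replicates to the observed design.

The conditional-Bernoulli draw is exact, not approximate: a dynamic
program computes the Poisson-binomial tail probabilities
q(i, t) = P(Σ_{j ≥ i} Y_j = t), and coordinates are drawn sequentially
with P(Y_i = 1 | t remaining) = π_i · q(i+1, t−1) / q(i, t). A
rejection sampler (draw independent Bernoullis, accept if the sum
matches) targets the same law and serves as the test oracle at small n,
alongside brute-force enumeration of all subsets. An alternative null —
permuting y directly within the logistic framework — would change the
null law slightly; the exact conditional draw was chosen because it
reproduces the stated conditional distribution without approximation.

Degenerate covariate fits fail loudly: rank-deficient designs report
the collinear columns, and logistic separation raises an error
(penalized fits are out of scope).

## The forest core

The forest behind the statistic is implemented in numba rather than
delegated to a general-purpose library, for one reason: the
permutation test refits the forest B+1 times per test and the
validation suite runs hundreds of tests, and at n ≈ 50 general
implementations spend an order of magnitude more time in per-tree
bookkeeping than in tree building (measured ≈ 115 ms vs ≈ 7 ms per
100-tree forest). The core is deliberately minimal:

* CART trees grown on bootstrap samples (n draws with replacement),
  `mtry` candidate features per split, maximizing variance reduction.
  For a 0/1 response, binary Gini impurity 2p(1−p) is proportional to
  the node variance p(1−p), so variance splitting selects exactly the
  Gini splits; one builder therefore serves both tasks, with leaf
  means as predictions — class-1 probabilities in classification
  (the probability-forest convention) and response means in
  regression.
* `mtry = max(1, round(mtry_fraction × n_features))`, with
  `mtry_fraction = 0.025` by default, applied to the actual
  (augmented, filtered) feature count — the matrix the forest sees.
* Minimum node size (below which a node is not split): 10 for
  probability classification, 5 for regression — the conventions of
  the probability-forest literature. No depth limit.
* A unit test cross-checks the statistic against scikit-learn's
  `RandomForestClassifier` OOB decision function on matched data; the
  two agree to well under a point of Brier score in the mean.

Samples that no tree leaves out of bag are excluded from the error
mean (and counted); with ≥ 500 trees and n ≈ 50 non-coverage is
essentially impossible (probability ≈ n·(1 − 1/e·…) ≈ 50·0.366⁵⁰⁰),
but exclusion keeps the statistic well defined at small tree counts.

**Seeding.** A master seed spawns two independent streams: one for
forest fits (one child per replicate, one per repeat, one per tree)
and one for the permutation/regeneration draws. Changing B or
`n_repeats` therefore never correlates the two sources, and a fixed
master seed reproduces the entire `TestResult` bitwise.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_permutations` (B) | 999 | p-value resolution 1/(B+1) = 0.001; simulation drivers use 99 or 49 |
| `n_trees` | 500 | stabilizes the OOB error; more trees barely help because permutation noise dominates |
| `mtry_fraction` | 0.025 | ≈ 2–3% of features per split works well for both clustered and diffuse signals |
| `n_repeats` | 3 | averaging independent forests roughly halves the statistic's variance |
| `min_node_size` | 10 / 5 | probability-forest / regression-forest conventions |
| `max_sparsity` | 0.96 | drop features absent in > 96% of samples; mild filtering, mostly a speed win |
| `outcome_type` | auto | binary iff exactly two distinct values; explicit override available because the statistic branches on it |

## The synthetic community generator

The simulation suite needs data with the statistical structure of a
real rarefied 16S survey without bundling one. `synth_community`
produces:

* a random rooted binary tree over p taxa (recursive uniform splits of
  a shuffled taxon list);
* a heavy-tailed base composition: Brownian motion down the tree
  (sd 1.0 per edge) plus independent log-normal heterogeneity
  (sd 1.5), so related taxa have related mean abundances and a few
  taxa dominate;
* per-sample structure: every sample adds its own Brownian
  perturbation on the tree (sd 0.3 per edge) — whole clades fluctuate
  up or down together across samples — plus per-taxon log-normal noise
  (sd 1.5), making individual taxa far noisier than their clade
  aggregates, as in real data;
* multinomial counts at a fixed depth (default 20,000), so every
  sample's counts sum to the depth exactly, as after rarefaction.

At the defaults (n = 50, p = 200, depth = 20,000) roughly a third of
the table's entries are zero and the most abundant taxon carries
≈ 20% of reads.

A **lineage registry** names clades for planting clustered signals:
lineage A (~15% of taxa, abundance share calibrated to 21%), B ⊂ A
(~5% of taxa, 11% abundance), C disjoint from A (~13% of taxa, 12%
abundance), and further disjoint clades D, E, … for lineage sweeps.
Abundance shares are calibrated by a multiplicative fixed point on the
expected per-sample composition, so realized shares track the targets
regardless of tail settings. The 5% clustered signal set is nested in
the 15% one by construction; random signal sets are prefixes of a
seed-determined taxon permutation, which nests densities for a common
seed.

**Outcome scenarios.** With s_i = Σ_{j∈S} x_ij (optionally per-taxon
mean-normalized, x_ij / x̄_j, so no single abundant taxon dominates;
taxa absent from every sample are dropped from the normalized sum —
they contribute nothing regardless — and the strict per-taxon error is
kept for direct calls):

* linear: y_i = β₀ + z_i + β·scale(s_i) + ε_i (continuous,
  β₀ = 10) or logit P(y_i = 1) = β₀ + z_i + β·scale(s_i) (binary,
  β₀ = 0), ε ~ N(0, σ²) with σ = 1 (no covariate) or 3 (with
  covariate);
* non-linear: x replaced by log₂(x + 1) inside the sum;
* interaction: signal term β·scale(s_i)·scale(s′_i) over two disjoint
  sets (β fixed at 1.33 continuous / 5 binary in the reference
  design);
* outliers: after the outcome is generated, the taxon order of k
  samples is shuffled, producing wholesale-different profiles;
* covariates: z = 0, z ~ N(0, 1) (independent), or
  z = scale(Σ_{j∈A} x_ij) + N(0, 1) (correlated with the microbiome).

`estimate_error_rate` runs the full pipeline over independently seeded
replicates and reports the rejection fraction at a nominal level with
its Wilson 95% interval — type-I error for β = 0 specs, power
otherwise.

**What the generator does not emulate**, and hence what passing
simulations do not establish for real data: taxonomic identity and
realistic tree shapes (real phylogenies are non-uniformly balanced);
the extreme sparsity of ASV-level tables with thousands of taxa;
technical structure (batch effects, variable library sizes before
rarefaction, contamination); and ecological interactions beyond the
covariance induced by shared clade factors. Results on synthetic data
demonstrate the test's operating characteristics under the designed
conditions, not its power on any particular real cohort.

## Validation problem sizes

The validation suite scales the reference study down to keep it
desk-runnable: type-I error uses 200 Monte-Carlo runs per S0 variant
(binary outcome, n = 50, p = 200, depth 20,000) at B = 99, 100 trees,
single repeat; the same runs feed a Kolmogorov–Smirnov uniformity
check of the null p-values. Power checks use B = 49 with paired seeds
across compared arms (identical datasets, so arm differences are not
drowned in Monte-Carlo noise): monotonicity over β ∈ {0, 1, 2, 3}
(50 runs per point), the clade-feature ablation at β = 1.5 (~50%
power, 200 runs), and outlier robustness at β = 2.5 (~70% power,
80 runs). `scripts/acceptance.py` recomputes the three type-I error
percentages from scratch at the same settings.

## Known limitations

* Refitting a forest per permutation is inherently compute-heavy;
  B = 999 with 500 trees and 3 repeats is minutes, not seconds, per
  dataset on one core.
* Power for phylogenetically *random* (non-clustered) signals is the
  method's known weak spot; kernel- and score-based community tests
  can dominate there.
* The binary-with-covariates null relies on the fitted logistic model;
  gross misspecification of the outcome–covariate relation propagates
  into the regenerated null (the continuous case is
  distribution-free given the linear fit).
* Rejected-variant statistics (training error, 0.632/0.632+ rules,
  binary-prediction OOB error) and omnibus combinations over multiple
  weighting schemes are deliberately not implemented.
* Only dense TSV tables and Newick trees are read; BIOM-HDF5 is out of
  scope.
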