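# Methods

`catsplitrf` implements random forests for regression, binary and multiclass
classification, and right-censored survival outcomes, built around one
question: how should a binary tree split on a *nominal* predictor — a
categorical variable whose `k` categories carry no order?

## The splitting problem

A split on a nominal predictor assigns each category to one of the two child
nodes.  There are `S(k, 2) = 2^(k-1) - 1` such 2-partitions, so the
exhaustive search (**Partition**) is exponential in `k`, and implementations
that store the assignment in a machine word cap `k` at 32/53/64.  The
package stores category sets as arbitrary-precision bit masks, so there is
no word-size cap; a configurable `partition_cap` (default 25) still stops
the exhaustive search before the enumeration itself becomes intractable.

For regression and binary classification a classical result removes the
problem: sort the categories by their within-category outcome mean (for a
0/1 outcome, the proportion of ones), treat the sorted categories as
ordinal, and the best of the `k - 1` threshold splits attains the exhaustive
optimum.  **Order(split)** applies this ordering in every node;
**Order(once)** computes it a single time on the full training data, which
also sidesteps the *absent levels* problem — in deep nodes many categories
are no longer present, and per-node methods have no defined side for them at
prediction time.

No loss-free ordering exists for multiclass or survival outcomes, so the
package uses two heuristics:

* **Multiclass** — build the `k x c` class-probability matrix `P` (row
  `p^a` = class frequencies within category `a`), form the weighted
  covariance `Sigma = 1/(n-1) * sum_a n_a (p^a - pbar)(p^a - pbar)^T`, and
  sort categories by the scores `S_a = v . p^a` of the first principal
  component `v` of `Sigma`.
* **Survival** — sort categories by the mean of the per-observation
  log-rank scores `a_i = delta_i - sum_{j<=gamma_i} delta_j/(N - gamma_j + 1)`,
  computed over the observations ranked by time.

**Dummy** coding (`k-1` indicators, first category as reference; one-hot
optional) and **Ignore** (codes used as ordinal in label-sort order)
complete the five methods.

Split quality is the decrease in Gini impurity (classification), the
decrease in the residual sum of squares (regression), or the squared
standardized two-sample log-rank statistic `(O - E)^2 / V` over the pooled
distinct event times (survival).  Trees aggregate by majority vote (ties to
the lowest class index), arithmetic mean, or the average of per-tree
Nelson-Aalen cumulative-hazard curves on the union event-time grid.

## Numerical and design choices

* **Log-rank score denominator.**  The per-observation scores use the
  running at-risk correction `N - gamma_j + 1` (the rank of observation `j`
  itself), which makes the scores sum to zero exactly — the defining sanity
  property.  An alternative reading with the constant denominator
  `N - gamma_i + 1` inside the sum is available as `printed_form=True` for
  comparison; it does not preserve the zero sum.  Ties are resolved into a
  strict total order (time ascending, events before censorings, then input
  order), which keeps the zero-sum identity exact even with tied times.
* **Weighted mean `pbar`.**  `pbar` is the count-weighted mean of the rows
  of `P`, so `Sigma` is a genuine weighted covariance; an unweighted mean is
  available via `weighted_covariance(..., weighted_mean=False)`.
* **Eigenvector sign and ties.**  The first principal component is
  sign-fixed so its largest-magnitude entry (first such on ties) is
  positive.  Orderings are only meaningful up to full reversal, and trees
  are invariant to reversal, so near-tied top eigenvalues are harmless.
* **Deterministic ties.**  Every ordering breaks score ties by ascending
  category index; categories absent from the data at hand are appended in
  index order and flagged.
* **Partition / Order(split) tree identity.**  For regression and binary
  classification both routes evaluate candidate gains through the same
  vectorized kernel (candidate sets as 0/1 rows times per-category
  sufficient statistics), so common candidates get bit-identical gains.
  The exhaustive search additionally resolves gain ties in favour of the
  mean-ordering prefix — the equivalence theorem guarantees one attains the
  optimum — and orients splits so the low-outcome-mean side goes left.
  Forests grown with the two methods from the same seed are therefore
  identical tree for tree, which the tests check on the induced partitions
  of bootstrap indices.
* **Thresholds.**  Numeric splits sit at midpoints between adjacent
  distinct values; ordinal and recoded-nominal splits at half-integer ranks.
* **Forest defaults.**  50 trees, bootstrap of size `n` with replacement,
  no depth cap, minimal node sizes 1 / 5 / 3 for classification /
  regression / survival (common reference-implementation defaults; the
  comparison protocol tunes only `mtry`).  Growth stops when a node is pure,
  has fewer than twice the minimal node size, or no candidate has positive
  gain.
* **RNG.**  One master seed; per-tree child streams via `SeedSequence`
  spawning; absent-level random assignments at prediction time use a
  dedicated stream, so predicting never perturbs training reproducibility.
* **Absent levels at prediction.**  Categories with no side in a stored
  split (or labels never seen in training) follow `absent_level_policy`:
  `"random"` (default; seed-reproducible, and the more robust choice) or
  `"left"`; `None` raises an error naming the offending labels.  Dummy
  coding routes unknown labels as all-zero indicator rows, i.e. like the
  reference category.

## Simulation scenarios

The generators produce paired train/validation replicates with `p = 4`
nominal predictors under four outcomes; their defaults are the study
conditions and are not tuning knobs.

* **Digit** — digits 0-9 uniform; the linear predictor is
  `eta = #odd - #even`.  Regression `y = eta` (deterministic, as defined);
  binary `y = 1[#odd > #even]`; multiclass the per-predictor parity pattern.
  The "16 classes" reading: counting combinations of (#odd, #even) would
  give only 5 classes at `p = 4`, so the class is the parity *pattern*
  (2^4 = 16), which matches the SNP and Group constructions exactly.
* **SNP** — genotypes 0/1/2 under Hardy-Weinberg equilibrium at minor
  allele frequency 0.25, purely heterozygous effect of size 3:
  `eta = 3 * #(genotype == 1)`.  Regression adds N(0, 1) noise ("simple
  linear model"); binary uses a logit model with intercept
  `-effect * p * 2 * maf * (1 - maf)` so prevalence is about one half;
  multiclass is the heterozygosity pattern.
* **Group** — 10 equally frequent categories whose effects differ between
  two random observation groups; each (group, predictor, category) effect is
  drawn once per replicate from Uniform(1, 10) (continuous; an integer
  option exists).  `eta` is the sum of applicable effects; the binary
  outcome thresholds `eta` at the median of the pooled train + validation
  replicate (computed before splitting); multiclass is the pattern of
  `effect >= 5` indicators.
* **Survival** — event times are exponential with rate `lambda` from the
  scenario's linear predictor.  For Group, `eta > 0` always and
  `lambda = eta` directly.  For Digit and SNP the literal rule is invalid
  (`eta` can be zero or negative), so the rate is `exp(z)` with `z` the
  per-dataset standardized `eta` — a strictly positive monotone repair that
  preserves the risk ordering; this is this package's own documented
  assumption, not part of the original construction.  Exactly
  `round(censor_fraction * n)` training observations (default 30%) are
  censored uniformly on `(0, T)`; validation data is never censored.
  Censoring draws come from a spawned RNG stream, so event times are
  identical across censoring fractions and the censoring sweep is paired.

What the generators do *not* emulate: predictor correlation, noise
categories without effect, missing values, covariate shift, or real
linkage-disequilibrium structure in SNPs.  Passing the comparison here shows
the splitting methods behave as designed under clean latent-order (Digit),
sparse-effect (SNP) and order-free (Group) signals; it does not by itself
predict margins on messy real data.

## Evaluation protocol

Per replicate: simulate `n` training and `n` validation observations; tune
`mtry` by five-fold CV (grid `1..p`, or ten evenly distributed values
between 1 and the number of encoded columns for Dummy — rounded linspace,
endpoints inclusive, deduplicated); refit 50 trees at the tuned value; score
on validation with MSE / misclassification proportion / integrated Brier
score.  All methods see byte-identical replicates, enabling the two-sided
paired t-test against Partition (identical error vectors give p = 1 by
convention; zero-variance nonzero differences give p = 0).  Real datasets
use 10/5-fold nested CV with the corrected resampled t-test (variance
multiplier `1/J + n_test/n_train`, J - 1 degrees of freedom).
Partition-limit failures are recorded as missing and excluded pairwise.

The integrated Brier score uses inverse-probability-of-censoring weights
from the Kaplan-Meier estimate of the censoring distribution on the
evaluation data, with the left-continuous `G(t-)` at event times; the
integration horizon defaults to the 95th percentile of the evaluation event
times (a reporting choice — the original horizon is unstated) and the
integral is a trapezoid over the prediction grid.  With uncensored
evaluation data (the protocol's case) all weights are 1.

## Problem sizes

Desk-scale defaults keep every study runnable on one CPU in minutes: 20
replicates per study (the full 100 is one argument away), 50-tree forests,
`n = 100`, 10-tree forests for the tree-identity checks, and 100 trees for
the category-availability curve (500 in the original design).  The
censoring-trend check runs at the endpoints 0 and 0.9 with a fixed
`mtry = 2` (the trend is qualitative and does not depend on tuning).

## Known limitations

* No variable importance, out-of-bag error, probability forests, or
  missing-value handling.
* Survival splitting uses the log-rank statistic only (no C-index
  splitting), and survival trees can be slow for large `n` because risk
  tables are rebuilt per node.
* The exhaustive Partition search is exponential by nature; above
  `partition_cap` it raises rather than degrades.
* Tree growing is single-threaded; determinism is guaranteed per seed.
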