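# Methods

This note records the modeling assumptions, numerical choices, and known
limitations of `rsaweight`, in the spirit of a statistics package's
model documentation.  Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Data model

An RDM is stored as its upper-triangle vector in row-major order over
the condition order (the `itertools.combinations` / `scipy.pdist`
convention); every module shares this canonical pair order, and
square-form I/O validates symmetry (1e-9) and a zero diagonal.  Four
metric tags are distinguished: `squared_euclidean` (activation-derived),
`judged_distance` (behavioral, metric unspecified by design — on-screen
distances are stored as given and never assumed Euclidean or squared),
`predicted` (model output, may be negative after intercept alignment),
and `rank_percentile` (display only; mid-rank percentiles on (0, 100]).

## Multi-arrangement averaging

Each behavioral trial yields pairwise distances for a subset of images
at an arbitrary scale.  Trials are combined by alternately (a) rescaling
every trial by its least-squares projection onto the current average
over its own pairs and (b) recomputing the per-pair mean of the rescaled
trials, until convergence.  Two details matter:

- **Normalization.** The update is linear in the current average, so the
  iteration is a power iteration on a non-negative linear operator; the
  raw average need not converge in scale.  The average is renormalized
  to unit RMS each step, convergence is declared when the relative L2
  change of the normalized vector falls below 1e-8 (max 1000
  iterations), and the final RDM is reported at unit RMS since absolute
  scale is meaningless.
- **Weights.** The per-pair weight is the number of trials covering the
  pair (the evidence count).  Because every trial contributing to a pair
  shares that pair's weight, the weighted per-pair mean reduces to the
  plain mean over contributing trials; evidence counts are kept in the
  diagnostics.

A session is averageable only if every pair is covered by at least one
trial; otherwise a coverage error lists the missing pairs.  Trial
consistency (QC) correlates each trial with the running average of its
predecessors over shared pairs, Fisher-z averaging the correlations.
Each incoming trial is least-squares rescaled to the running average
before entering it — without this, the arbitrary per-trial scales
contaminate the running average and even noiseless sessions fail to
reach r = 1.

## Predictor sets

Conceptual models hold per-image values in [0, 1] (binary before
merging) on labeled dimensions grouped as parts / colors / textures /
contours (features) and subordinate / basic / superordinate
(categories).  Highly correlated dimensions are merged by averaging
their image values (single linkage at Pearson r >= 0.9 by default,
configurable; merging is restricted to within a group so feature and
category models remain separable).  Zero-variance dimensions are
excluded with a warning since their correlation is undefined.

A predictor set is the pairs x K matrix of single-dimension RDMs —
squared pairwise differences for scalar dimensions, squared Euclidean
distances for multi-unit feature maps — plus a constant confound-mean
column acting as the unpenalized intercept.  Combining two sets
concatenates their columns under namespaced ids and keeps exactly one
confound column; exact duplicate columns are flagged but retained (the
ridge penalty handles collinearity).

## Non-negative ridge fitting

The objective is `(1/2N)||y - b - Zw||^2 + (lambda/2)||w||^2` with
`w >= 0` and `b` unpenalized.  Predictors are standardized to zero mean
and unit population standard deviation using training rows only
(zero-variance columns are zeroed and flagged); the intercept is
profiled out exactly by centering.  The solver is cyclical coordinate
descent on the Gram form with non-negative clipping, tolerance 1e-8 on
the maximum coordinate change, at most 10000 sweeps; a numba-compiled
kernel is used when available, with an identical pure-Python fallback.
Solutions match an independent quadratic-programming oracle (augmented
non-negative least squares on the same objective) to 1e-6 in objective
value, and KKT conditions hold at active bounds (verified in the test
suite on randomized instances).

**Penalty grid.** A pure L2 penalty drives the weights to zero only in
the infinite-lambda limit, so the grid anchor follows the glmnet
convention: `lambda_max = 1e3 * max_j |z_j . y| / N` (numerically-zero
solution), with 30 log-spaced values down to `1e-4 * lambda_max`,
visited in descending order with warm starts.

## Cross-validation

Outer folds hold out `n_heldout_images` images (default 8, matching the
84/92 train/test split of the study design).  Training pairs are those
with both images in the training set; predicted pairs are those with
both images held out (`both-heldout`, the default and the strictest
generalization claim) or at least one held out (`any-heldout`, selectable).
The penalty for each outer fold is chosen by nested image-level
cross-validation: the training images are partitioned into 5 inner
folds, and the lambda minimizing pooled squared prediction error on
inner held-out pairs is selected, ties broken toward stronger
regularization.

- **Coverage.** Folds repeat until every pair is predicted at least
  once.  Each fold's held-out set contains one uniformly drawn
  *uncovered* pair plus randomly drawn further images; this keeps folds
  freshly randomized while guaranteeing termination (uniform resampling
  alone has a coupon-collector tail that can exceed any fixed fold cap).
- **Combination across folds.** Per-pair predictions are averaged over
  the folds that produced them *after removing each fold's intercept*;
  the mean fold intercept is restored as one global constant.  Fold
  intercepts are training means that systematically exclude the held-out
  pairs, and mixing them into the predictions injects
  training-set-composition noise that biases rank correlations downward
  under the null; with intercept-aligned combination the cross-validated
  tau-a of label-permuted targets is centered at zero (verified by a
  100-permutation null in the acceptance suite).  A global constant
  cannot affect rank-based evaluation.
- **Audit.** The fold log records held-out images and predicted pairs
  per fold; an audit asserts structurally that no predicted pair ever
  had a member image in the fold's training set.  Identical spec and
  seed reproduce the fold log and predictions bit-identically.

The fold-averaged weights are reported on the original predictor scale
(standardized-scale weights divided by the training standard
deviations), preserving non-negativity.

## Evaluation

Kendall's tau-a uses the total pair count as denominator, counting ties
as neither concordant nor discordant.  Two implementations must agree:
exact vectorized pair enumeration for vectors up to 1024 elements, and a
Knight-style O(n log n) counter (lexicographic sort, tie-run counting,
mergesort inversion count) above.  Note that tau-a of a tied vector with
itself is below 1 by exactly the tie fraction; this is a property of the
statistic, not a defect — identical subjects therefore yield a noise
ceiling of (1, 1) only for tie-free RDMs.

The noise ceiling rank-transforms each subject RDM and averages tau-a of
each subject against the all-subject mean rank RDM (upper) and the
leave-one-out mean (lower).  The rank-transform variant is used because
the evaluation statistic is a rank correlation; its exact tightness
under tau-a is not guaranteed (the construction is canonical for
Spearman-type statistics).  The lower bound is capped at the upper bound
(sampling noise can rarely invert them for tau-a).  The upper bound
retains a small positive bias under independent subjects because each
subject enters its own average; the leave-one-out bound is the unbiased
side.

## Inference

Wilcoxon signed-rank tests drop exact zeros and mid-rank tied absolute
values.  For n <= 25 the null distribution is exact, computed by dynamic
programming over doubled mid-ranks (doubling makes mid-ranks integral);
one-sided p is the upper tail of W+, two-sided p doubles the smaller
tail (capped at 1).  Above n = 25 a tie-corrected normal approximation
with continuity correction is used; the two algorithms agree within 0.01
at n = 16 on random draws (tested).  FDR control is Benjamini–Hochberg
at q = 0.05 via statsmodels, validated in the tests against the literal
step-up definition.  Pairwise model comparisons (two-sided) and
model-vs-zero tests (one-sided) form two separate FDR families; whether
the original analyses pooled them is unknown, so the families are kept
apart and configurable.

## Synthetic study generator

The generator reproduces the statistical structure the analysis
assumes, not images: 92 abstract conditions, 16 subjects, ~20 binary
feature dimensions (independent Bernoulli, prevalence 0.3) and 14
category indicators forming a strict nesting (8 subordinate within 4
basic within 2 superordinate; every image carries exactly one label per
level).  These dimension counts are scaled down from the full label sets
(120 feature / 114 category dimensions) to keep default runs fast; the
counts are scenario fields.  Ground-truth judgment weights are set per
group — categories dominate (basic/superordinate 1.0, subordinate 0.6,
features 0.25), reflecting that nearly all participants in this paradigm
report arranging by category — with an optional per-dimension
multiplier range for heterogeneous-weight scenarios (the recovery
scenario uses Uniform(0.1, 1) over 20 feature dimensions).  Subject RDMs
add i.i.d. Gaussian noise (sd = 0.3 x true-RDM RMS by default) truncated
at zero; this is the simplest noise model that exercises the ceiling and
the Wilcoxon machinery, chosen in the absence of an empirical noise
model.

Synthetic layers draw each dimension's source label from a
group-mixing profile (early layers: feature groups; late layers:
category groups), broadcast it over units with Uniform(0.5, 1.5)
loadings, and add unit Gaussian noise (sd 0.5) — enough signal for the
early-feature / late-category correlation gradient to emerge while
keeping layers imperfect models of the judgments.  Multi-arrangement
sessions show all images on trial 1 and uniform random subsets
(Normal(16, 3.4) sizes, reflecting the observed session shape of ~22
trials with ~16 objects) thereafter, each scaled by Uniform(0.5, 2) with
truncated Gaussian noise at 10% of the true-distance RMS.  The adaptive
weak-evidence subset selection of the real task is deliberately not
reproduced; random subsets cover pairs less efficiently but have no
selection-induced bias.

What passing tests on these data do **not** show: robustness to
non-Gaussian or heteroscedastic judgment noise, to systematic individual
differences (subjects here share one true RDM), to correlated feature
labels, or to the dimensionality of real network layers (hundreds of
feature maps vs. ~a dozen here).

## Problem sizes and runtime

Default test and acceptance runs use: the full 92-image / 16-subject
scenario for parameter recovery (20 seeds) and the end-to-end
qualitative-pattern check; 16–48 image scenarios for the
permutation-null and ceiling-containment simulations (100 runs each);
2000 replicates for the null-FDR calibration.  The complete suite runs
in a few minutes on one CPU.

## Known limitations

- The iterative averaging procedure's trial weights and convergence rule
  are this package's documented choices; the original algorithm's
  internals are not published in a reimplementable form.
- The noise-ceiling bounds are canonical for Spearman-type statistics
  and used here with tau-a without a tightness guarantee.
- Nested-CV penalty selection is noisy at small image counts (few
  held-out pairs per inner fold); it is biased toward strong
  regularization on structureless targets but does not concentrate
  sharply on the grid maximum.
- The exact glmnet penalty parameterization used originally is unknown;
  solver correctness is asserted against the stated objective, not
  against a specific implementation.
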