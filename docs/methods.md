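# Methods

This note documents the models, conventions and numerical choices
behind `elmcortex`, in the order the pipeline applies them, followed
by what the synthetic-data generator does and does not emulate, and
known limitations.

## Feature schema

A subject is described by 340 cortical features: 5 morphometric
measures × 68 parcels (34 standard cortical parcellation regions per
hemisphere). Features carry 1-based indices in five contiguous measure
blocks — thickness 1–68, surface area 69–136, volume 137–204, folding
index 205–272, curvature 273–340. Within each block the 34
left-hemisphere parcels come first, in the order FreeSurfer prints
regions in its per-hemisphere parcellation summary tables (bankssts …
insula), then the 34 right-hemisphere parcels in the same order. This
within-block order is the one choice the schema leaves open; the
downstream mathematics is order-invariant, and the chosen order makes
parsed FreeSurfer summaries land in schema order with no permutation.
Parcellation summaries are read from the standard stats-table dialect
(`#`-prefixed metadata, a `# ColHeaders` line, whitespace-delimited
rows); measures map to the `ThickAvg`, `SurfArea`, `GrayVol`,
`FoldInd` and `MeanCurv` columns.

Labels are `+1` (patient) / `−1` (control) everywhere. This matches
the single-output-node ELM target construction and makes the
threshold-0 decision rule uniform across classifiers; the tie
`score = 0` resolves to `+1`.

## Normalization

Min–max scaling of every column to [0, 1] is computed over the whole
cohort *before* cross-validation: the pipeline's fixed stage order
puts normalization ahead of any model fitting (normalize → select →
classify). This leaks the held-out
subject's contribution to each column's min/max into training — a
deliberate fidelity choice. A `per_fold_normalization` switch refits
the scaling on each training fold only, for leakage-sensitivity
studies; it is off by default. Constant columns normalize to all
zeros: the feature stays in [0, 1] and is uninformative, consistent
with its Fisher score of 0.

## Fisher score

`F(i) = [(x̄⁺ᵢ−x̄ᵢ)² + (x̄⁻ᵢ−x̄ᵢ)²] / [s⁺ᵢ² + s⁻ᵢ²]` with per-class
*sample* variances (n−1 divisors), the standard convention for this
criterion; it also reduces small-n bias. Degenerate columns: 0/0 → 0,
positive/0 → +∞ with a flag on the ranking. Ranking ties break by
ascending feature index, so runs are deterministic. The score is
invariant under positive affine per-feature transforms, hence
identical before and after min–max normalization (up to ties on
constant columns) — a property the tests exercise.

## Sequential forward selection

Greedy forward selection over a candidate pool, criterion-agnostic:
each step adds the feature maximizing the criterion of the augmented
subset, ties to the lowest index. The search runs to
`min(max_steps, |pool|)` and returns the *best prefix* of the path
rather than stopping at the first decline, because wrapper criteria
routinely dip locally and recover. In the pipeline the criterion is
the LOOCV testing accuracy of the configured criterion classifier
(ELM by default, so the reported selection path is one sequence
evaluated by all classifiers); the pool defaults to the top 46
Fisher-ranked features and `max_steps` to 19. Criterion evaluations
are cached per subset and use a fixed evaluation seed, making the
greedy path deterministic.

## Extreme learning machine

Input weights and biases are drawn uniformly on [−1, 1] (configurable)
from a seeded generator; the hidden layer is the logistic sigmoid,
20 nodes by default. Output weights are `β = H†T` computed by dense
SVD with singular values below `max(N, L)·eps·σ_max` treated as zero,
which yields the minimum-norm least-squares solution under rank
deficiency. There is no regularization beyond that cutoff. Because
the only stochasticity is the hidden-layer draw, the reported training
accuracy mean ± SD for the ELM is taken over repeated random
re-initializations (20 by default, seeds `s, s+1, …`). The SVM's
training spread, which has no initialization randomness, is reported
fold-wise instead; the two SD columns therefore measure different
things, and this divergence is intentional and documented here.

With `L ≥ N` distinct samples the hidden matrix has full row rank with
probability one, so the network interpolates its targets; the tests
use this as an invariant (zero training error at `L = N`, monotone
training accuracy in `L`).

## SVM baselines

The quadratic-programming solver is scikit-learn's `SVC`; this package
owns the protocol around it. Hyperparameters come from exponential
grids `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `γ ∈ {2⁻¹⁵, …, 2³}`, scored by
stratified 5-fold inner cross-validation; ties resolve to the smallest
`C`, then the smallest `γ`. By default the grid search runs once per
experimental dataset on the full cohort (the default protocol)
rather than nested inside each LOOCV fold; a `nested` option
re-tunes per fold. Decision scores are oriented positive-toward-patient
and thresholded at 0.

**Known artifact.** On strongly separable cohorts many grid points tie
at the maximal inner-CV accuracy, and the smallest-`C` tie rule (or a
genuine inner-CV win for tiny `C`) can select a model whose decision
is dominated by the class-balance term. Inner CV uses balanced
stratified folds and cannot see the failure mode, but LOOCV training
sets are imbalanced by exactly one subject, so such a model votes for
the training majority — the complement of the held-out class — and
scores near 0%. Rows with ~50% training accuracy and a collapsed test
score in the curve reports mark these experimental datasets. This is
a faithful consequence of the protocol (threshold 0, accuracy-scored
grids), visible on synthetic data because near-ties are common there.

## Evaluation protocol

LOOCV: one fold per subject; the ELM is re-initialized per fold from
independent substreams of the master seed (`SeedSequence.generate_state`),
so folds are exchangeable yet the run is exactly reproducible.
ROC curves sweep thresholds over the per-fold scores (scikit-learn
backend); AUC is the trapezoid area, equal to the pairwise
rank-comparison statistic with half credit for ties — the tests verify
that identity against a brute-force oracle.

Permutation test: the *full* label vector is shuffled before each
LOOCV loop (so every training fold of a permutation run sees permuted
labels; the common reading of "cross-validation on the permuted
training set"), the whole LOOCV rate is recomputed, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` — the add-one estimator,
never exactly zero, and conservative in the presence of ties between
observed and null rates. `n_perm` defaults to 1000 for desk-scale
runs; 10000 is a config value away.

Paired comparison of per-ED accuracies uses a two-sided paired t-test;
the zero-variance degenerate cases are reported explicitly (equal
vectors → `t=0, p=1`; constant nonzero difference → signed ∞, `p=0`)
rather than as NaN.

Sample-size sweep: for each even size, a balanced sub-cohort (half
patients, half controls) is drawn and evaluated by LOOCV; requesting
the full cohort size keeps the original subject order so the result
coincides with the plain LOOCV run.

## Synthetic cohorts and their oracles

The generator draws class-conditional Gaussians with equal covariance:
the five measures of one parcel share an equicorrelated noise
component (default correlation 0.3), parcels are independent, and
informative features get a `+d·σ` mean shift in patients. Defaults
emulate a typical cohort for this problem: 55 patients + 55 controls, 340
features, effect size `d = 1.5` on 10 informative features placed in
parcels repeatedly reported as structurally atypical in this disorder
(cuneus, lingual, transverse/middle temporal, pars opercularis,
paracentral, precentral, insula). Raw values are mapped onto
measure-specific plausible scales (thickness ≈ 2.5 ± 0.25 mm, area ≈
700 ± 90 mm², …); the map is affine per measure and therefore
irrelevant after normalization, but it makes fixtures look like real
summary tables.

Equal-covariance Gaussianity is the minimal structure under which
Fisher ranking and linear decision rules are provably sensible and the
Bayes-optimal accuracy has the closed form `Φ(Δ/2)`, `Δ` the
Mahalanobis separation (computed parcel-blockwise). That gives two
independent oracles — the accuracy ceiling and the exact
likelihood-ratio scorer — against which the pipeline is tested.

What the generator does **not** emulate: site/scanner effects, age and
medication covariates, non-Gaussian tails, long-range anatomical
correlations between parcels, FreeSurfer segmentation noise, or class
covariance differences. Passing tests therefore demonstrate that the
machinery is correct and calibrated under the stated model, not that
any particular accuracy is attainable on real imaging cohorts.

## Problem sizes in the test suite and acceptance script

The suite exercises full-scale cohorts (110 × 340) where the checked
property needs them (recovery, ELM-vs-Bayes) and reduced sizes where
it does not: the permutation-calibration study uses 100 replicate
40-subject null cohorts × 99 permutations with a 10-node ELM on 6
features — the p-value estimator and LOOCV code paths are the
full-scale ones, only the problem size is reduced — and the
protocol-report reproducibility checks run the CLI on 20-subject
cohorts with small `k_max`/pool sizes. The acceptance script runs the
curve/SFS/validation protocol on a full 110 × 340 default cohort with
`k_max = 15`, pool 15, 8 SFS steps and 199 permutations.

## Known limitations

- The whole-cohort normalization and once-per-ED grid search are the
  default protocol, including its mild optimistic bias; the hygienic
  variants (`per_fold_normalization`, `nested`) exist but are not the
  defaults.
- The small-`C` SVM degeneracy described above can null individual
  experimental datasets on nearly separable cohorts.
- LOOCV accuracies on ~110 subjects have ~±5-point Monte-Carlo
  granularity; single-ED comparisons between classifiers are noisy,
  which is why significance claims go through the paired test over
  many EDs and the permutation test.
- No AUC confidence intervals; wall-clock timings are logged but are
  hardware-bound and deliberately not part of any assertion.
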