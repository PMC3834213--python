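# elmcortex

Classification of case/control cohorts from cortical-morphometry
feature tables, built around an **extreme learning machine (ELM)**
classifier with Fisher-score and sequential-forward-selection feature
selection, SVM baselines, leave-one-out cross-validation, ROC/AUC and
permutation-test significance. The package targets structural-MRI
studies of the kind used for ADHD diagnosis support, where each
subject is summarized by five morphometric measures (average cortical
thickness, surface area, gray-matter volume, folding index, intrinsic
curvature) on each of 68 cortical parcels — 340 features per subject —
and the question is whether those features separate patients from
controls, and which of them carry the signal.

It is a library first (importable API plus `examples/` scripts), with
a thin CLI (`elmcortex simulate|rank|curve|sfs|validate|sweep`) for
running the pipeline from a shell.

## The method

Given feature vectors `x_k` with labels `y_k ∈ {+1 patient, −1 control}`:

1. **Normalization.** Every feature is min–max scaled to [0, 1] over
   the cohort.
2. **Fisher-score ranking.** Each feature `i` is scored by

       F(i) = [ (x̄⁺ᵢ − x̄ᵢ)² + (x̄⁻ᵢ − x̄ᵢ)² ] / [ s⁺ᵢ² + s⁻ᵢ² ]

   (class means vs whole-cohort mean over pooled per-class sample
   variances); features are sorted by descending `F`. The top-k
   prefixes form nested *experimental datasets* ED₁ ⊂ ED₂ ⊂ … that are
   evaluated to produce an accuracy-vs-k curve.
3. **Sequential forward selection (SFS).** Starting from the empty
   set, greedily add the pool feature that maximizes the LOOCV
   accuracy of the classifier on the augmented subset; keep the best
   prefix of the path.
4. **ELM.** A single-hidden-layer feedforward network whose input
   weights `W` and biases `b` are random (uniform on [−1, 1], never
   trained). With hidden output matrix `H = g(XWᵀ + b)` (logistic
   sigmoid `g`, 20 hidden nodes by default), the output weights are
   the minimum-norm least-squares solution

       β = H† T,

   with `H†` the Moore–Penrose pseudoinverse and `T` the ±1 targets —
   training is a single SVD-based linear solve. Prediction scores are
   `g(XWᵀ + b) β`, thresholded at 0.
5. **Baselines.** Linear- and RBF-kernel SVMs with `(C, γ)` chosen by
   stratified inner cross-validation over exponential grids
   (`C ∈ 2⁻⁵…2¹⁵`, `γ ∈ 2⁻¹⁵…2³`).
6. **Evaluation.** LOOCV testing accuracy; ROC curves and AUC from the
   per-fold continuous scores; significance by rebuilding the whole
   LOOCV loop on label-permuted cohorts (`p = (1 + #{null ≥ observed})
   / (1 + n_perm)`); paired t-tests between classifiers; and a
   balanced sub-cohort sweep of accuracy versus sample size.

A built-in synthetic-cohort generator (Gaussian class-conditional
model, equicorrelated noise within each parcel, a configurable set of
mean-shifted informative features) makes the whole pipeline testable
without any imaging data and provides closed-form oracles, e.g. the
Bayes-optimal accuracy `Φ(Δ/2)` with `Δ` the Mahalanobis separation of
the class means.

## Worked example

```sh
python examples/02_rank_features.py
```

```
rank  score   feature
   1   0.709  [238, FI, L-Insula]  <- planted
   2   0.639  [140, V, L-Cuneus]  <- planted
   3   0.553  [271, FI, R-Transversetemporal]  <- planted
   ...
```

All ten features planted by the generator occupy the top ten Fisher
ranks; a score of 0.7 means the class means differ by roughly one
pooled within-class standard deviation. Continuing with selection and
validation (`python examples/04_sfs_and_validation.py`, 40-subject
cohort):

```
 ED  Added feature                                      ELM train        ELM test
---------------------------------------------------------------------------------
  1  [271, FI, R-Transversetemporal]                93.88±1.28             90.00
  2  [148, V, L-Lingual]                            97.50±0.00             87.50
  3  [101, SA, L-Transversetemporal]                97.88±0.92             90.00
  4  [119, SA, R-Parsopercularis]                   98.00±1.03             92.50*
  5  [72, SA, L-Cuneus]                             99.25±1.18             90.00

selected subset: (271, 148, 101, 119)
```

SFS keeps the four-feature prefix (best LOOCV accuracy 92.5%); the
final validation step then reports each classifier's AUC on the
held-out fold scores and the permutation p-value of the observed
generalization rate.

The same stages are available from the shell:

```sh
elmcortex simulate --out cohort.csv --seed 42
elmcortex curve --table cohort.csv --seed 7 --k-max 20 --outdir out/
elmcortex sfs   --table cohort.csv --seed 7 --outdir out/
```

Feature tables are plain CSV/TSV (one subject per row, a `diagnosis`
column coded `1/-1` or `ADHD/control`); per-subject FreeSurfer
parcellation summaries can be assembled into the 340-feature schema
with `parse_freesurfer_stats` (see `examples/06_freesurfer_import.py`).

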