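"""Evaluation protocol: LOOCV, ROC/AUC, permutation tests, paired
comparison of classifiers, and the sample-size sweep.

LOOCV holds out each subject once, trains on the remaining N-1 and
scores the held-out row; testing accuracy is the percentage of correct
fold predictions.  Stochastic classifiers (ELM) are re-initialized per
fold from independent substreams of the master seed, so folds are
exchangeable yet the whole run is reproducible.

The permutation test rebuilds the full LOOCV loop on label-shuffled
cohorts to form a null distribution of the generalization rate; the
p-value uses the add-one estimator (1 + #{null >= observed}) /
(1 + n_perm), which is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifiers import Classifier
from .errors import ValidationError
from .schema import FeatureTable


def _fold_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent 32-bit substream seeds for the n folds."""
    return np.random.SeedSequence(master_seed).generate_state(n)


@dataclass
class ClassifierEval:
    """One classifier's numbers for one experimental dataset."""

    name: str
    train_acc_mean: float  # %
    train_acc_sd: float    # %
    test_acc: float        # % (LOOCV)
    fold_scores: np.ndarray
    fold_predictions: np.ndarray


@dataclass
class EvaluationResult:
    ed_id: Optional[int]
    feature_subset: tuple[int, ...]
    true_labels: np.ndarray
    results: dict[str, ClassifierEval]

    def __getitem__(self, name: str) -> ClassifierEval:
        return self.results[name]


def loocv(table: FeatureTable, subset: Sequence[int],
          classifiers, seed: int = 0, n_init_repeats: int = 20,
          ed_id: Optional[int] = None,
          train_stats: bool = True) -> EvaluationResult:
    """Leave-one-out cross-validation of one or more classifiers.

    ``subset`` holds 1-based feature indices.  Training-accuracy
    spread: for stochastic classifiers the mean +/- SD is taken over
    ``n_init_repeats`` random re-initializations on the full subset
    table; for deterministic classifiers it is taken fold-wise.
    """
    if hasattr(classifiers, "fit"):
        classifiers = [classifiers]
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValidationError("feature subset is empty")
    n_pos, n_neg = table.class_counts()
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("LOOCV needs >= 2 subjects per class")

    sub = table.select_features(subset)
    X, y = sub.values, sub.labels
    n = sub.n_subjects
    seeds = _fold_seeds(seed, n)

    results = {}
    for clf in classifiers:
        fold_scores = np.empty(n)
        fold_preds = np.empty(n, dtype=int)
        fold_train_accs = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for k in range(n):
            mask[k] = False
            fitted = clf.fit(X[mask], y[mask], int(seeds[k]))
            fold_scores[k] = float(fitted.scores(X[k])[0])
            fold_preds[k] = int(fitted.predict(X[k])[0])
            if train_stats:
                fold_train_accs[k] = 100.0 * float(
                    np.mean(fitted.predict(X[mask]) == y[mask]))
            mask[k] = True
        test_acc = 100.0 * float(np.mean(fold_preds == y))
        if not train_stats:
            train_mean = train_sd = float("nan")
        elif clf.stochastic:
            accs = np.empty(n_init_repeats)
            base = int(seeds[-1]) ^ 0x5DEECE66  # distinct from fold streams
            for r in range(n_init_repeats):
                fitted = clf.fit(X, y, (base + r) % (2 ** 32))
                accs[r] = 100.0 * float(np.mean(fitted.predict(X) == y))
            train_mean, train_sd = float(accs.mean()), float(accs.std(ddof=1))
        else:
            train_mean = float(fold_train_accs.mean())
            train_sd = float(fold_train_accs.std(ddof=1))
        results[clf.name] = ClassifierEval(clf.name, train_mean, train_sd,
                                           test_acc, fold_scores, fold_preds)
    return EvaluationResult(ed_id, subset, y.copy(), results)


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC by threshold sweep over the continuous prediction scores.

    AUC is the trapezoidal area, equal to the pairwise rank statistic
    P(score_patient > score_control) with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == -1)):
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, pos_label=1,
                                  drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_sk_auc(fpr, tpr)))


@dataclass
class PermutationResult:
    observed_rate: float      # %
    null_rates: np.ndarray    # %
    p_value: float


def permutation_test(table: FeatureTable, subset: Sequence[int],
                     classifier: Classifier, n_perm: int = 1000,
                     seed: int = 0) -> PermutationResult:
    """Classifier significance by label permutation.

    The full label vector is shuffled before each LOOCV loop, so every
    training fold of a permutation run sees permuted labels; the
    observed LOOCV rate is compared against the null distribution of
    rates so obtained.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = loocv(table, subset, classifier, seed=seed,
                     train_stats=False)[classifier.name].test_acc
    rng = np.random.default_rng(seed)
    sub = table.select_features(subset)  # column lookup hoisted out of the loop
    null_rates = np.empty(n_perm)
    for p in range(n_perm):
        perm_labels = rng.permutation(table.labels)
        perm_table = sub.with_labels(perm_labels)
        null_rates[p] = loocv(perm_table, subset, classifier, seed=seed + 1 + p,
                              train_stats=False)[classifier.name].test_acc
    p_value = (1.0 + float(np.sum(null_rates >= observed - 1e-9))) / (1.0 + n_perm)
    return PermutationResult(observed, null_rates, p_value)


def paired_comparison(acc_a: Sequence[float], acc_b: Sequence[float]):
    """Two-sided paired t-test on per-experimental-dataset accuracies.

    Degenerate cases are reported explicitly rather than as NaN: equal
    vectors give (0.0, 1.0); a constant nonzero difference has zero
    variance and gives (signed inf, 0.0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("accuracy vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 paired values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def sample_size_sweep(table: FeatureTable, subset: Sequence[int],
                      classifiers, sizes: Sequence[int], seed: int = 0,
                      n_repeats: int = 1) -> pd.DataFrame:
    """LOOCV accuracy as a function of cohort size.

    For each size a balanced random sub-cohort (half patients, half
    controls) is drawn and evaluated; ``size == n_subjects`` keeps the
    full cohort in its original order.  Returns a tidy table with
    columns (size, repeat, classifier, train_acc_mean, train_acc_sd,
    test_acc).
    """
    if hasattr(classifiers, "fit"):
        classifiers = [classifiers]
    n_pos, n_neg = table.class_counts()
    if n_pos != n_neg:
        raise ValidationError("sample-size sweep requires a balanced cohort")
    for s in sizes:
        if s % 2 != 0:
            raise ValidationError(f"sizes must be even (got {s})")
        if s > table.n_subjects:
            raise ValidationError(f"size {s} exceeds cohort size {table.n_subjects}")
        if s < 4:
            raise ValidationError("sizes must be >= 4 (2 per class)")
    rng = np.random.default_rng(seed)
    pos_rows = np.flatnonzero(table.labels == 1)
    neg_rows = np.flatnonzero(table.labels == -1)
    rows = []
    for size in sizes:
        for rep in range(n_repeats):
            if size == table.n_subjects:
                chosen = np.arange(table.n_subjects)
            else:
                half = size // 2
                chosen = np.concatenate([
                    rng.choice(pos_rows, half, replace=False),
                    rng.choice(neg_rows, half, replace=False)])
            sub = FeatureTable(table.values[chosen], table.labels[chosen],
                               [table.subject_ids[i] for i in chosen],
                               list(table.descriptors), table.normalized)
            res = loocv(sub, subset, classifiers, seed=seed + size + rep)
            for name, ev in res.results.items():
                rows.append({"size": size, "repeat": rep, "classifier": name,
                             "train_acc_mean": ev.train_acc_mean,
                             "train_acc_sd": ev.train_acc_sd,
                             "test_acc": ev.test_acc})
    return pd.DataFrame(rows)
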