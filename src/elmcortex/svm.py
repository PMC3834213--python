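"""Maximum-margin (SVM) baselines with grid-searched hyperparameters.

The quadratic-programming solver is delegated to scikit-learn's SVC;
this module owns parameter plumbing, the exponential search grids,
stratified inner cross-validation, deterministic tie-breaking and
score orientation (+ toward the patient class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import ValidationError

#: Exponentially growing default grids (standard practice for SVC tuning):
#: C = 2^-5, 2^-3, ..., 2^15 and gamma = 2^-15, 2^-13, ..., 2^3.
DEFAULT_COST_GRID = tuple(2.0 ** e for e in range(-5, 17, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 5, 2))


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValidationError(f"unsupported kernel {self.kernel!r}")
        if not self.cost_grid or any(c <= 0 for c in self.cost_grid):
            raise ValidationError("cost grid must be non-empty and positive")
        if self.kernel == "rbf" and (
                not self.gamma_grid or any(g <= 0 for g in self.gamma_grid)):
            raise ValidationError("gamma grid must be non-empty and positive")


def _check_two_class(y: np.ndarray) -> None:
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValidationError("both classes must be present")


def _make_svc(config: SVMConfig, C: float, gamma: Optional[float]) -> SVC:
    if config.kernel == "linear":
        return SVC(kernel="linear", C=C)
    return SVC(kernel="rbf", C=C, gamma=gamma)


def svm_grid_search(X, y, config: SVMConfig):
    """Pick (C, gamma) by stratified inner CV on the training data only.

    Returns (best_C, best_gamma_or_None, table) where table rows are
    (C, gamma, mean inner-CV accuracy).  Ties go to the smallest C,
    then the smallest gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_class(y)
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    n_splits = min(config.inner_cv_folds, n_min)
    if n_splits < 2:
        raise ValidationError("need >= 2 subjects per class for inner CV")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)

    gammas = config.gamma_grid if config.kernel == "rbf" else (None,)
    table = []
    best = None  # (acc, C, gamma)
    for C in sorted(config.cost_grid):
        for gamma in (sorted(gammas) if config.kernel == "rbf" else gammas):
            clf = _make_svc(config, C, gamma)
            acc = float(np.mean(cross_val_score(clf, X, y, cv=cv)))
            table.append((C, gamma, acc))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    _, best_c, best_gamma = best
    return best_c, best_gamma, table


def svm_train_predict(X_train, y_train, X_test, config: SVMConfig,
                      C: float, gamma: Optional[float] = None):
    """Fit an SVC and score test rows.

    Returns (scores, labels): decision-function scores oriented so that
    positive means the patient (+1) class, thresholded at 0.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_test.ndim == 1:
        X_test = X_test[None, :]
    if X_test.shape[1] != X_train.shape[1]:
        raise ValidationError("train/test feature dimension mismatch")
    y_train = np.asarray(y_train)
    _check_two_class(y_train)
    clf = _make_svc(config, C, gamma)
    clf.fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    # sklearn orients decision_function toward classes_[1]; with {-1,+1}
    # labels classes_ is [-1, 1], i.e. + already points to patients
    assert clf.classes_[1] == 1
    labels = np.where(scores >= 0.0, 1, -1)
    return scores, labels
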