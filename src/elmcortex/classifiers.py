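"""Uniform classifier contract used by the evaluation protocol.

A classifier object exposes

    name        short identifier used in reports ("elm", "svm_linear", ...)
    stochastic  True if refitting with a new seed can change the model
    fit(X, y, seed) -> fitted object with .scores(X) and .predict(X)

so that LOOCV, SFS and the permutation test are agnostic to what is
being evaluated.  All decision rules threshold a continuous score at 0
(score >= 0 -> patient class +1).
"""

from __future__ import annotations

from typing import Optional, Protocol

import numpy as np

from .elm import ELMConfig, elm_predict, elm_train
from .svm import SVMConfig, svm_grid_search, svm_train_predict


class FittedClassifier(Protocol):
    def scores(self, X) -> np.ndarray: ...
    def predict(self, X) -> np.ndarray: ...


class Classifier(Protocol):
    name: str
    stochastic: bool

    def fit(self, X, y, seed: int) -> FittedClassifier: ...


class _FittedELM:
    def __init__(self, model):
        self.model = model

    def scores(self, X):
        return elm_predict(self.model, X)[0]

    def predict(self, X):
        return elm_predict(self.model, X)[1]


class ELMClassifier:
    """Extreme learning machine under the common contract."""

    stochastic = True

    def __init__(self, config: ELMConfig = ELMConfig(), name: str = "elm"):
        self.config = config
        self.name = name

    def fit(self, X, y, seed: int) -> _FittedELM:
        return _FittedELM(elm_train(X, y, self.config.with_seed(seed)))


class _FittedSVM:
    def __init__(self, X_train, y_train, config, C, gamma):
        # SVC refits cheaply; keep the training set and delegate per call
        from sklearn.svm import SVC  # local import keeps module load light
        if config.kernel == "linear":
            self._clf = SVC(kernel="linear", C=C)
        else:
            self._clf = SVC(kernel="rbf", C=C, gamma=gamma)
        self._clf.fit(X_train, y_train)

    def scores(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._clf.decision_function(X)

    def predict(self, X):
        return np.where(self.scores(X) >= 0.0, 1, -1)


class SVMClassifier:
    """SVM baseline; hyperparameters fixed up front or tuned per fit.

    The default protocol tunes (C, gamma) once per experimental dataset by
    inner CV on the whole cohort (call :meth:`tune`), then runs LOOCV
    with the chosen values; set ``nested=True`` to re-run the grid
    search inside every training fold instead.
    """

    stochastic = False

    def __init__(self, config: SVMConfig, C: Optional[float] = None,
                 gamma: Optional[float] = None, nested: bool = False,
                 name: Optional[str] = None):
        self.config = config
        self.C = C
        self.gamma = gamma
        self.nested = nested
        self.name = name or f"svm_{config.kernel}"

    def tune(self, X, y) -> tuple[float, Optional[float]]:
        self.C, self.gamma, _ = svm_grid_search(X, y, self.config)
        return self.C, self.gamma

    def fit(self, X, y, seed: int) -> _FittedSVM:
        C, gamma = self.C, self.gamma
        if self.nested or C is None:
            C, gamma, _ = svm_grid_search(X, y, self.config)
        return _FittedSVM(X, y, self.config, C, gamma)


class ConstantClassifier:
    """Always predicts one class; a degenerate reference for tests."""

    stochastic = False

    def __init__(self, label: int = 1, name: str = "constant"):
        self.label = label
        self.name = name

    def fit(self, X, y, seed: int):
        label = self.label

        class _Fitted:
            def scores(self, X):
                X = np.atleast_2d(np.asarray(X, dtype=float))
                return np.full(X.shape[0], float(label))

            def predict(self, X):
                X = np.atleast_2d(np.asarray(X, dtype=float))
                return np.full(X.shape[0], label, dtype=int)

        return _Fitted()
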