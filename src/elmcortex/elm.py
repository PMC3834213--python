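"""Extreme learning machine (ELM) for binary classification.

A single-hidden-layer feedforward network whose input weights W and
hidden biases b are drawn at random and never trained.  With hidden
output matrix H[k, j] = g(w_j . x_k + b_j), g the logistic sigmoid,
the output weights are the minimum-norm least-squares solution

    beta = pinv(H) T,       T = targets coded +1 (patient) / -1 (control)

via the Moore-Penrose pseudoinverse, so "training" is a single linear
solve.  Prediction scores are g(X W^T + b) beta and the decision rule
is score >= threshold -> +1 (threshold 0 by default).

With L hidden nodes and N <= L distinct samples the network can
interpolate the targets exactly (H has full row rank with probability
one under continuous random weights), which is the basis of several of
the test invariants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {"sigmoid": _sigmoid}


@dataclass(frozen=True)
class ELMConfig:
    """Hyperparameters of the ELM.

    Defaults: 20 hidden nodes, logistic sigmoid activation, input
    weights and biases uniform on [-1, 1], decision threshold 0.
    """

    n_hidden: int = 20
    activation: str = "sigmoid"
    weight_low: float = -1.0
    weight_high: float = 1.0
    bias_low: float = -1.0
    bias_high: float = 1.0
    seed: int = 0
    decision_threshold: float = 0.0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValidationError("n_hidden must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")

    def with_seed(self, seed: int) -> "ELMConfig":
        return ELMConfig(self.n_hidden, self.activation, self.weight_low,
                         self.weight_high, self.bias_low, self.bias_high,
                         int(seed), self.decision_threshold)


@dataclass
class ELMModel:
    input_weights: np.ndarray   # [n_hidden x n_features]
    hidden_biases: np.ndarray   # [n_hidden]
    output_weights: np.ndarray  # beta, [n_hidden]
    config: ELMConfig
    n_features: int

    def hidden_layer(self, X: np.ndarray) -> np.ndarray:
        g = _ACTIVATIONS[self.config.activation]
        return g(X @ self.input_weights.T + self.hidden_biases)


def elm_train(X: np.ndarray, y: np.ndarray, config: ELMConfig) -> ELMModel:
    """Train an ELM: seeded random hidden layer + one least-squares solve.

    beta is the minimum-norm minimizer of ||H beta - T||_2, obtained by
    SVD-based least squares with singular-value cutoff
    max(N, L) * eps * sigma_max.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be a matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    if y.shape != (X.shape[0],) or not np.all(np.isin(y, (-1, 1))):
        raise ValidationError("y must be a +1/-1 vector matching X rows")
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValidationError("both classes must be present in y")

    rng = np.random.default_rng(config.seed)
    L, d = config.n_hidden, X.shape[1]
    W = rng.uniform(config.weight_low, config.weight_high, size=(L, d))
    b = rng.uniform(config.bias_low, config.bias_high, size=L)
    H = _ACTIVATIONS[config.activation](X @ W.T + b)
    T = y.astype(float)
    beta = _pinv_solve(H, T)
    return ELMModel(W, b, beta, config, d)


def _pinv_solve(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares beta = pinv(H) T via dense SVD.

    Singular values below max(N, L) * eps * sigma_max are treated as
    zero, so rank deficiency yields the minimum-norm solution.
    """
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros(H.shape[1])
    cutoff = max(H.shape) * np.finfo(H.dtype).eps * s[0]
    keep = s > cutoff
    coeff = np.zeros_like(s)
    coeff[keep] = (U.T @ T)[keep] / s[keep]
    return Vt.T @ coeff


def elm_predict(model: ELMModel, X: np.ndarray):
    """Score and classify; returns (scores, labels in {+1, -1})."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"X has {X.shape[1]} features, model expects {model.n_features}")
    scores = model.hidden_layer(X) @ model.output_weights
    labels = np.where(scores >= model.config.decision_threshold, 1, -1)
    return scores, labels


def training_accuracy(model: ELMModel, X: np.ndarray, y: np.ndarray) -> float:
    """Resubstitution accuracy in percent."""
    _, pred = elm_predict(model, X)
    return 100.0 * float(np.mean(pred == y))


def repeated_init_training_stats(X, y, config: ELMConfig, n_repeats: int = 20):
    """(mean, sample SD) of training accuracy (%) over random re-inits.

    The ELM's only stochasticity is the hidden-layer draw, so the
    spread over seeds seed, seed+1, ... quantifies init sensitivity.
    """
    if n_repeats < 2:
        raise ValidationError("n_repeats must be >= 2")
    accs = np.empty(n_repeats)
    for r in range(n_repeats):
        model = elm_train(X, y, config.with_seed(config.seed + r))
        accs[r] = training_accuracy(model, X, y)
    return float(accs.mean()), float(accs.std(ddof=1))


def save_model(model: ELMModel, path) -> None:
    """Serialize a model as JSON text."""
    payload = {
        "config": {
            "n_hidden": model.config.n_hidden,
            "activation": model.config.activation,
            "weight_low": model.config.weight_low,
            "weight_high": model.config.weight_high,
            "bias_low": model.config.bias_low,
            "bias_high": model.config.bias_high,
            "seed": model.config.seed,
            "decision_threshold": model.config.decision_threshold,
        },
        "n_features": model.n_features,
        "input_weights": model.input_weights.tolist(),
        "hidden_biases": model.hidden_biases.tolist(),
        "output_weights": model.output_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ELMModel:
    payload = json.loads(Path(path).read_text())
    return ELMModel(
        input_weights=np.array(payload["input_weights"], dtype=float),
        hidden_biases=np.array(payload["hidden_biases"], dtype=float),
        output_weights=np.array(payload["output_weights"], dtype=float),
        config=ELMConfig(**payload["config"]),
        n_features=int(payload["n_features"]),
    )
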