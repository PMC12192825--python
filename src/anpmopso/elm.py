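"""Extreme learning machine: random hidden layer, least-squares readout.

A single-hidden-layer network whose input weights and biases are random
(seed-controlled, uniform on [−1, 1]) and whose output weights are the ridge
pseudo-inverse solution on one-hot targets.  Training is a single linear
solve, which keeps per-mask fitness evaluation cheap inside the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


class ParameterError(ValueError):
    pass


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ELMModel:
    input_weights: np.ndarray   # (H, F)
    biases: np.ndarray          # (H,)
    output_weights: np.ndarray  # (H, C)
    classes_: np.ndarray        # original class values, sorted
    ridge: float

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.input_weights.T + self.biases)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(np.asarray(X, dtype=float)) @ self.output_weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


def train_elm(
    train_X: np.ndarray,
    train_y: np.ndarray,
    n_hidden: int = 100,
    seed: int = 0,
    ridge: float = 1e-6,
) -> ELMModel:
    """Fit an ELM on (n_samples, n_features) data with arbitrary class labels.

    The readout solves the regularized normal equations
    ``(GᵀG + ridge·I) β = Gᵀ T`` for one-hot targets T, equivalent to the
    ridge Moore–Penrose solution.
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ParameterError("need a 2-D feature matrix with >= 1 feature")
    if n_hidden < 1:
        raise ParameterError("n_hidden must be >= 1")
    if X.shape[0] != y.shape[0]:
        raise ParameterError("X and y disagree on sample count")

    classes, codes = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)

    G = _sigmoid(X @ W.T + b)
    T = np.zeros((X.shape[0], classes.size))
    T[np.arange(X.shape[0]), codes] = 1.0
    beta = scipy.linalg.solve(
        G.T @ G + ridge * np.eye(n_hidden), G.T @ T, assume_a="pos"
    )
    return ELMModel(
        input_weights=W, biases=b, output_weights=beta, classes_=classes, ridge=ridge
    )


def classification_accuracy(model: ELMModel, X: np.ndarray, y: np.ndarray) -> float:
    """Percentage of correctly classified instances (0–100)."""
    y = np.asarray(y)
    if y.size == 0:
        raise ParameterError("empty evaluation set")
    unseen = ~np.isin(y, model.classes_)
    if unseen.any():
        warnings.warn(
            f"{int(unseen.sum())} instances have labels unseen in training; "
            "counted as errors",
            stacklevel=2,
        )
    pred = model.predict(np.asarray(X, dtype=float))
    correct = (pred == y) & ~unseen
    return 100.0 * float(np.count_nonzero(correct)) / y.size
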