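"""Multinomial (softmax) regression trained by full-batch gradient descent.

The output layer maps a descriptor x to net inputs z = W^T x + b and
class probabilities softmax(z).  Training minimizes the mean
cross-entropy over the n training samples,

    J(W; b) = (1/n) sum_i C(Y_i, O_i) + (lambda/2) ||W||^2,
    C(Y_i, O_i) = - sum_j Y_ij log O_ij,

with analytic gradients

    grad_W = (1/n) X^T (O - Y) + lambda W,
    grad_b = (1/n) column sums of (O - Y),

and updates W := W - eta grad_W, b := b - eta grad_b.  Biases are not
regularized.  The L-moment layer upstream is a fixed transform; only W
and b are learned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelParams",
    "SoftmaxRegression",
    "one_hot_encode",
    "softmax",
    "cost",
    "gradients",
    "fit",
    "predict",
]

_LOG_CLAMP = 1e-15

#: Reproducible fixed initialization for k = 6: every weight row starts at
#: these six values and the bias starts at the vector below.
_FIXED_W_ROW = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
_FIXED_B = np.array([0.01, 0.1, 0.1, 0.1, 0.1, 0.1])


@dataclass
class ModelParams:
    """Learned weights plus the hyperparameters used to obtain them."""

    W: np.ndarray
    b: np.ndarray
    eta: float = 0.01
    lam: float = 0.01
    iterations: int = 500
    k: int = 6

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("model parameters must be finite")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class TrainingTrace:
    cost_per_iteration: list[float] = field(default_factory=list)


def one_hot_encode(labels, k: int) -> np.ndarray:
    """One-hot matrix for 1-based class indices in {1..k}."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-D")
    if labels.size and (labels.min() < 1 or labels.max() > k):
        raise ValueError(f"labels must lie in 1..{k}")
    Y = np.zeros((labels.size, k))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y


def softmax(Z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("net inputs must be finite")
    E = np.exp(Z - Z.max(axis=-1, keepdims=True))
    return E / E.sum(axis=-1, keepdims=True)


def cost(Y: np.ndarray, O: np.ndarray, W: Optional[np.ndarray] = None, lam: float = 0.0) -> float:
    """Mean cross-entropy plus (lam/2) ||W||^2 (biases unpenalized).

    Probabilities at target positions are clamped at 1e-15 before the log.
    """
    Y = np.asarray(Y, float)
    O = np.asarray(O, float)
    if Y.shape != O.shape:
        raise ValueError("Y and O must have the same shape")
    ce = -np.sum(Y * np.log(np.maximum(O, _LOG_CLAMP))) / Y.shape[0]
    if lam and W is not None:
        ce += 0.5 * lam * float(np.sum(np.asarray(W) ** 2))
    return float(ce)


def gradients(
    X: np.ndarray, Y: np.ndarray, O: np.ndarray, W: np.ndarray, lam: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the regularized cross-entropy w.r.t. W and b."""
    X, Y, O, W = (np.asarray(a, float) for a in (X, Y, O, W))
    n = X.shape[0]
    if Y.shape != O.shape or Y.shape[0] != n or W.shape != (X.shape[1], Y.shape[1]):
        raise ValueError("shape mismatch among X, Y, O, W")
    R = O - Y
    grad_w = X.T @ R / n + lam * W
    grad_b = R.sum(axis=0) / n
    return grad_w, grad_b


class SoftmaxRegression(BaseEstimator, ClassifierMixin):
    """Softmax output layer trained by deterministic full-batch descent.

    Parameters
    ----------
    eta : float
        Learning rate in (0, 1]; default 0.01.
    iterations : int
        Number of full-batch gradient steps; default 500.
    lam : float
        L2 penalty strength on the weights (not the biases); default 0.01.
    random_state : int
        Seeds the uniform [0, 0.1] weight initialization.
    init : {"uniform", "fixed"}
        "fixed" starts every weight row at (0.1, ..., 0.6) and the bias at
        (0.01, 0.1, 0.1, 0.1, 0.1, 0.1); it requires exactly 6 classes.

    Attributes
    ----------
    W_ : ndarray of shape (n_features, n_classes)
    b_ : ndarray of shape (n_classes,)
    classes_ : ndarray of the sorted class labels seen in ``fit``
    cost_trace_ : list of the objective value at each iteration
    """

    def __init__(
        self,
        eta: float = 0.01,
        iterations: int = 500,
        lam: float = 0.01,
        random_state: int = 0,
        init: str = "uniform",
    ):
        self.eta = eta
        self.iterations = iterations
        self.lam = lam
        self.random_state = random_state
        self.init = init

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = self.classes_.size
        if k < 2:
            raise ValueError("need at least 2 classes")
        if X.shape[0] < k:
            raise ValueError("need at least as many samples as classes")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        n, m = X.shape
        Y = one_hot_encode(y_idx + 1, k)

        if self.init == "fixed":
            if k != _FIXED_W_ROW.size:
                raise ValueError("fixed initialization requires exactly 6 classes")
            W = np.tile(_FIXED_W_ROW, (m, 1))
            b = _FIXED_B.copy()
        elif self.init == "uniform":
            rng = np.random.default_rng(self.random_state)
            W = rng.uniform(0.0, 0.1, size=(m, k))
            b = np.zeros(k)
        else:
            raise ValueError(f"unknown init {self.init!r}")

        trace: list[float] = []
        for _ in range(self.iterations):
            O = softmax(X @ W + b)
            J = cost(Y, O, W, self.lam)
            if not np.isfinite(J):
                raise FloatingPointError(
                    f"non-finite cost after {len(trace)} iterations; "
                    "reduce eta or rescale the descriptors"
                )
            trace.append(J)
            gw, gb = gradients(X, Y, O, W, self.lam)
            W -= self.eta * gw
            b -= self.eta * gb

        self.W_ = W
        self.b_ = b
        self.n_features_in_ = m
        self.cost_trace_ = trace
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.W_.shape[0]:
            raise ValueError(
                f"descriptor dimension {X.shape} does not match model "
                f"({self.W_.shape[0]} features)"
            )
        return X @ self.W_ + self.b_

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X):
        # argmax breaks ties toward the lowest class index
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]

    @property
    def params_(self) -> ModelParams:
        check_is_fitted(self, "W_")
        return ModelParams(
            self.W_, self.b_, self.eta, self.lam, self.iterations, self.classes_.size
        )

    def save(self, directory: Path | str) -> None:
        """Serialize weights as CSV plus a JSON header."""
        check_is_fitted(self, "W_")
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "weights.csv", self.W_, delimiter=",")
        np.savetxt(out / "bias.csv", self.b_[None, :], delimiter=",")
        header = {
            "format_version": 1,
            "n_features": int(self.W_.shape[0]),
            "n_classes": int(self.W_.shape[1]),
            "classes": [str(c) for c in self.classes_],
            "eta": self.eta,
            "iterations": self.iterations,
            "lam": self.lam,
            "init": self.init,
            "random_state": self.random_state,
        }
        (out / "model.json").write_text(json.dumps(header, indent=2))
        np.savetxt(out / "cost_trace.csv", np.asarray(self.cost_trace_), delimiter=",")

    @classmethod
    def load(cls, directory: Path | str) -> "SoftmaxRegression":
        src = Path(directory)
        header = json.loads((src / "model.json").read_text())
        model = cls(
            eta=header["eta"],
            iterations=header["iterations"],
            lam=header["lam"],
            random_state=header["random_state"],
            init=header["init"],
        )
        model.W_ = np.loadtxt(src / "weights.csv", delimiter=",", ndmin=2)
        model.b_ = np.loadtxt(src / "bias.csv", delimiter=",").ravel()
        model.classes_ = np.asarray(header["classes"])
        model.n_features_in_ = header["n_features"]
        model.cost_trace_ = list(
            np.atleast_1d(np.loadtxt(src / "cost_trace.csv", delimiter=","))
        )
        return model


def fit(
    X,
    labels,
    eta: float = 0.01,
    iterations: int = 500,
    lam: float = 0.01,
    seed: int = 0,
    init: str = "uniform",
) -> tuple[ModelParams, TrainingTrace]:
    """Functional training interface; see :class:`SoftmaxRegression`."""
    model = SoftmaxRegression(
        eta=eta, iterations=iterations, lam=lam, random_state=seed, init=init
    ).fit(X, labels)
    return model.params_, TrainingTrace(model.cost_trace_)


def predict(X, model: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (1-based) and probabilities under ``model``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.W.shape[0]:
        raise ValueError("descriptor dimension does not match model")
    P = softmax(X @ model.W + model.b)
    return np.argmax(P, axis=1) + 1, P
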