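"""Extreme Learning Machine classification head.

A single-hidden-layer network whose hidden weights are drawn at random and
frozen; only the output weights beta are trained, in closed form, by ridge
regression against one-hot targets:

    primal (N > L):  beta = (I/C + H^T H)^{-1} H^T O
    dual   (N <= L): beta = H^T (I/C + H H^T)^{-1} O

where H is the N x L hidden-layer activation matrix (sigmoid), O the N x k
one-hot target matrix, and C > 0 the regularization constant.  As C grows
the solution approaches the minimum-norm Moore-Penrose solution H^+ O.
Class probabilities are a softmax over the linear readout h(x) beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = ["ElmModel", "ElmFitReport", "elm_init", "elm_fit", "elm_predict",
           "elm_loss"]


@dataclass
class ElmModel:
    """Random hidden layer plus (after fitting) solved output weights."""

    input_dim: int
    L: int
    seed: int
    weights: np.ndarray = field(repr=False)   # (input_dim, L)
    biases: np.ndarray = field(repr=False)    # (L,)
    C: float = 1.0
    beta: np.ndarray | None = field(default=None, repr=False)  # (L, classes)

    @property
    def fitted(self) -> bool:
        return self.beta is not None

    def hidden(self, Z: np.ndarray) -> np.ndarray:
        """Sigmoid hidden-layer activations H = sigma(Z W + b)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        if Z.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input features, got {Z.shape[1]}")
        return special.expit(Z @ self.weights + self.biases)


@dataclass
class ElmFitReport:
    train_error: float          # mean squared residual of H beta vs targets
    condition_estimate: float   # of the regularized Gram matrix


def elm_init(input_dim: int, L: int, seed: int) -> ElmModel:
    """Draw the fixed hidden layer: weights and biases uniform on (-1, 1)."""
    if L < 1:
        raise ValueError(f"hidden neuron count L must be >= 1, got {L}")
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    rng = np.random.default_rng(seed)
    return ElmModel(
        input_dim=input_dim, L=L, seed=seed,
        weights=rng.uniform(-1.0, 1.0, (input_dim, L)),
        biases=rng.uniform(-1.0, 1.0, L),
    )


def elm_fit(model: ElmModel, Z_train: np.ndarray, O: np.ndarray,
            C: float = 1e6) -> tuple[ElmModel, ElmFitReport]:
    """Solve the output weights by regularized least squares.

    Uses the dual form when N <= L (so the N x N system is the smaller one)
    and the primal form otherwise; for C -> inf both approach the
    Moore-Penrose solution.  Returns the fitted model and a fit report.
    """
    if C <= 0:
        raise ValueError(f"regularization constant C must be > 0, got {C}")
    Z_train = np.atleast_2d(np.asarray(Z_train, dtype=np.float64))
    O = np.atleast_2d(np.asarray(O, dtype=np.float64))
    if Z_train.shape[0] != O.shape[0]:
        raise ValueError(
            f"{Z_train.shape[0]} feature rows vs {O.shape[0]} target rows")
    H = model.hidden(Z_train)
    n, L = H.shape
    if n <= L:
        gram = H @ H.T + np.eye(n) / C
        beta = H.T @ np.linalg.solve(gram, O)
    else:
        gram = H.T @ H + np.eye(L) / C
        beta = np.linalg.solve(gram, H.T @ O)
    resid = H @ beta - O
    report = ElmFitReport(
        train_error=float(np.mean(resid ** 2)),
        condition_estimate=float(np.linalg.cond(gram)),
    )
    model.beta = beta
    model.C = float(C)
    return model, report


def elm_predict(model: ElmModel, Z: np.ndarray) -> np.ndarray:
    """Row-wise softmax class probabilities for feature rows Z."""
    if not model.fitted:
        raise RuntimeError("ELM has no output weights; call elm_fit first")
    logits = model.hidden(Z) @ model.beta
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def elm_loss(Y_pred: np.ndarray, Y_true: np.ndarray, theta: np.ndarray | None = None,
             eta: float = 0.0, over_features: int | None = None,
             eps: float = 1e-12) -> float:
    """Cross-entropy of predicted probabilities plus a ridge penalty.

    By default the negative log-likelihood is averaged over samples; passing
    ``over_features=K`` divides by a fixed feature length K instead (an
    alternative normalization convention).  ``eta * ||theta||^2`` is added
    when a penalized parameter vector is supplied.
    """
    Y_pred = np.atleast_2d(np.asarray(Y_pred, dtype=np.float64))
    Y_true = np.atleast_2d(np.asarray(Y_true, dtype=np.float64))
    if Y_pred.shape != Y_true.shape:
        raise ValueError(f"shape mismatch: {Y_pred.shape} vs {Y_true.shape}")
    ll = -(Y_true * np.log(np.clip(Y_pred, eps, None))).sum()
    denom = over_features if over_features is not None else Y_pred.shape[0]
    loss = ll / denom
    if theta is not None and eta != 0.0:
        loss += eta * float(np.sum(np.asarray(theta) ** 2))
    return float(loss)
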