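"""Regularized extreme learning machine (ELM) for multiclass classification.

An ELM is a single-hidden-layer feedforward network whose hidden
parameters (input weights ``A`` and biases ``b``) are drawn randomly —
here i.i.d. uniform on [-1, 1] — and never trained.  With the logistic
sigmoid ``g`` the hidden output matrix is ``H[i, j] = g(a_j . x_i + b_j)``.
Class labels are one-hot encoded with +1 for the true class and -1
elsewhere, and the output weights ``beta`` minimise the ridge objective

    1/2 ||beta||^2 + C/2 ||T - H beta||^2,

whose closed-form solution is ``beta = (I/C + H'H)^-1 H'T``.  For wide
hidden layers (N < L) the algebraically identical dual form
``beta = H'(I/C + HH')^-1 T`` is solved instead, so the linear system is
never larger than min(N, L).  Prediction scores are ``h(x) beta`` and the
label is the argmax over classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import expit

from .features import Standardizer

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1 / (1 + exp(-z)); the default ELM activation."""
    return expit(z)


@dataclass
class ElmModel:
    """A (possibly trained) regularized ELM.

    ``A`` (L x n) and ``b`` (L) are the frozen random hidden parameters;
    ``beta`` (L x m) exists only after training.  ``classes`` fixes the
    output-column ordering.  An optional fitted feature ``scaler`` is
    carried with the model and applied before scoring, so a serialized
    model is self-contained.
    """

    A: np.ndarray
    b: np.ndarray
    C: float
    classes: list[str]
    seed: int
    beta: np.ndarray | None = None
    scaler: Standardizer | None = None
    activation: Callable[[np.ndarray], np.ndarray] = field(
        default=sigmoid, repr=False, compare=False
    )

    @property
    def L(self) -> int:
        return self.A.shape[0]

    @property
    def n_features(self) -> int:
        return self.A.shape[1]


def init_hidden(n: int, L: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the random hidden layer: A (L x n) and b (L), U[-1, 1].

    The same seed always reproduces the same draw (PCG64 generator).
    """
    if n < 1 or L < 1:
        raise ValueError(f"need n >= 1 and L >= 1, got n={n}, L={L}")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1.0, 1.0, size=(L, n))
    b = rng.uniform(-1.0, 1.0, size=L)
    return A, b


def hidden_output(
    X: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] = sigmoid,
) -> np.ndarray:
    """Hidden-layer output matrix H (N x L), H[i, j] = g(a_j . x_i + b_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != A.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match hidden weights "
            f"({A.shape[1]} inputs)"
        )
    return activation(X @ A.T + b)


def infer_classes(labels: Sequence[str]) -> list[str]:
    """Class ordering used when none is supplied: first appearance."""
    return list(dict.fromkeys(labels))


def encode_labels(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    """Encode labels as an N x m matrix of -1 with +1 at the true class."""
    index = {c: j for j, c in enumerate(classes)}
    T = -np.ones((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        try:
            T[i, index[lab]] = 1.0
        except KeyError:
            raise ValueError(f"label {lab!r} not in classes {list(classes)}") from None
    return T


def decode_targets(T: np.ndarray, classes: Sequence[str]) -> list[str]:
    """Inverse of :func:`encode_labels` (argmax per row)."""
    return [classes[j] for j in np.argmax(T, axis=1)]


def _solve_beta(H: np.ndarray, T: np.ndarray, C: float, solver: str = "auto") -> np.ndarray:
    """Ridge solution of the ELM objective, via primal or dual normal equations.

    Both are SPD systems for C > 0 and are solved by Cholesky
    factorization (never an explicit inverse); a factorization failure
    falls back to a least-squares solve, logged.
    """
    N, L = H.shape
    if solver == "auto":
        solver = "primal" if N >= L else "dual"
    if solver == "primal":
        G = H.T @ H + np.eye(L) / C
        rhs = H.T @ T
        try:
            return cho_solve(cho_factor(G), rhs)
        except LinAlgError:
            logger.warning("Cholesky failed on the primal system; using lstsq")
            return np.linalg.lstsq(G, rhs, rcond=None)[0]
    elif solver == "dual":
        G = H @ H.T + np.eye(N) / C
        try:
            return H.T @ cho_solve(cho_factor(G), T)
        except LinAlgError:
            logger.warning("Cholesky failed on the dual system; using lstsq")
            return H.T @ np.linalg.lstsq(G, T, rcond=None)[0]
    raise ValueError(f"unknown solver {solver!r}")


def train(
    X: np.ndarray,
    labels: Sequence[str],
    C: float,
    L: int,
    seed: int,
    classes: Sequence[str] | None = None,
    scaler: Standardizer | None = None,
    solver: str = "auto",
) -> ElmModel:
    """Train a regularized ELM on an (already standardized) feature matrix.

    ``X`` is N x n; ``scaler``, if given, is only *stored* on the model
    for use at prediction time — the caller passes training features that
    are already transformed, keeping fit/apply responsibilities explicit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not C > 0:
        raise ValueError(f"regularization constant C must be positive, got {C}")
    if len(labels) != X.shape[0]:
        raise ValueError("one label per row required")
    class_list = list(classes) if classes is not None else infer_classes(labels)
    if len(class_list) < 1:
        raise ValueError("at least one class required")
    A, b = init_hidden(X.shape[1], L, seed)
    H = hidden_output(X, A, b)
    T = encode_labels(labels, class_list)
    beta = _solve_beta(H, T, C, solver=solver)
    return ElmModel(A=A, b=b, C=C, classes=class_list, seed=seed, beta=beta, scaler=scaler)


def predict_scores(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Network output f(x) = h(x) beta for each row of X (N x m)."""
    if model.beta is None:
        raise ValueError("model has not been trained (beta is unset)")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1) if X.size else X.reshape(0, model.n_features)
    if X.shape[0] == 0:
        return np.empty((0, len(model.classes)))
    if model.scaler is not None:
        from .features import apply_standardizer

        X = apply_standardizer(model.scaler, X)
    H = hidden_output(X, model.A, model.b, model.activation)
    return H @ model.beta


def predict_labels(model: ElmModel, X: np.ndarray) -> list[str]:
    """Argmax-decoded class per row; exact ties go to the lowest class index."""
    scores = predict_scores(model, X)
    winners = np.argmax(scores, axis=1)  # np.argmax takes the first maximum
    n_ties = int(np.sum((scores == scores[np.arange(len(winners)), winners][:, None]).sum(axis=1) > 1)) if len(winners) else 0
    if n_ties:
        logger.debug("%d tied score rows decoded to the lowest class index", n_ties)
    return [model.classes[j] for j in winners]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: ElmModel, path: str | Path) -> None:
    """Serialize a trained model to a single self-describing ``.npz`` file."""
    if model.beta is None:
        raise ValueError("refusing to serialize an untrained model")
    payload = {
        "format_version": np.array(MODEL_FORMAT_VERSION),
        "A": model.A,
        "b": model.b,
        "beta": model.beta,
        "C": np.array(model.C),
        "seed": np.array(model.seed),
        "classes": np.array(model.classes, dtype="U"),
    }
    if model.scaler is not None:
        payload["scaler_mu"] = model.scaler.mu
        payload["scaler_sigma"] = model.scaler.sigma
    np.savez(path, **payload)


def load_model(path: str | Path) -> ElmModel:
    """Load a model written by :func:`save_model`."""
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        scaler = None
        if "scaler_mu" in data:
            scaler = Standardizer(mu=data["scaler_mu"], sigma=data["scaler_sigma"])
        return ElmModel(
            A=data["A"],
            b=data["b"],
            C=float(data["C"]),
            classes=[str(c) for c in data["classes"]],
            seed=int(data["seed"]),
            beta=data["beta"],
            scaler=scaler,
        )
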