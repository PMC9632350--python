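"""Brain-age regression models.

Two regressors operate entirely in z-space (standardized FA in, standardized
age out):

* :class:`RidgeModel` — closed-form ridge regression with an unpenalized
  intercept. With centered predictors and target the intercept is exactly 0.
* :class:`ANNModel` — a single-hidden-layer perceptron with as many hidden
  neurons as input tracts (a square hidden weight matrix ``W``), ReLU
  activation, hidden biases initialized to 0, ``W`` initialized to the
  identity, and the output layer pre-trained as the ridge solution. At
  initialization the network therefore reproduces the ridge prediction for
  any input with non-negative pre-activations; training then lets hidden
  neurons absorb interactions between tracts while (empirically) retaining
  a dominant diagonal.

Hyperparameters (the L2 penalty ``alpha``) are tuned by exhaustive grid
search with cross-validation; after training, the hidden matrix is
magnitude-pruned until the network has at most one free parameter per
training sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CrossValidationError,
    NumericalError,
    ParameterError,
    PruningError,
)
from .preprocessing import Scaler
from .tracts import TRACT_NAMES

__all__ = [
    "RidgeModel",
    "ANNModel",
    "GridSearchResult",
    "fit_ridge",
    "loocv_mse",
    "ridge_loocv_mse",
    "grid_search_alpha",
    "ridge_grid",
    "ann_grid",
    "init_ann",
    "train_ann",
    "prune_ann",
    "predict_age",
]

_COND_LIMIT = 1e8  # invertibility threshold for the hidden matrix


# ---------------------------------------------------------------------------
# Ridge regression (closed form)
# ---------------------------------------------------------------------------


@dataclass
class RidgeModel:
    """Ridge solution in z-space: ``y = x @ coef + intercept``."""

    coef: np.ndarray
    intercept: float
    alpha: float

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeModel":
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
        )


def fit_ridge(X: np.ndarray, y: np.ndarray, alpha: float) -> RidgeModel:
    """Closed-form ridge with an unpenalized intercept.

    ``coef = (Xc' Xc + alpha I)^-1 Xc' yc`` on column-centered data;
    ``intercept = mean(y) - mean_row(X) @ coef``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("X must be 2-D with at least 2 rows")
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    A = Xc.T @ Xc + alpha * np.eye(X.shape[1])
    try:
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned normal equations")
        coef = np.linalg.solve(A, Xc.T @ yc)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"ridge normal equations singular: {exc}") from exc
    if not np.all(np.isfinite(coef)):
        raise NumericalError("ridge coefficients are non-finite")
    return RidgeModel(coef=coef, intercept=ym - xm @ coef, alpha=float(alpha))


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------


def loocv_mse(
    fit_fn: Callable[[np.ndarray, np.ndarray], "object"],
    X: np.ndarray,
    y: np.ndarray,
) -> float:
    """Leave-one-out MSE of an arbitrary fit function.

    ``fit_fn(X_train, y_train)`` must return an object with a
    ``forward(X)`` method. A fit failure on any fold is re-raised with the
    fold index attached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ParameterError("LOOCV needs at least 3 samples")
    errs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = fit_fn(X[mask], y[mask])
        except Exception as exc:  # noqa: BLE001 - annotate and propagate
            raise CrossValidationError(f"fit failed on LOOCV fold {i}: {exc}") from exc
        pred = np.asarray(model.forward(X[i : i + 1])).ravel()[0]
        errs[i] = (pred - y[i]) ** 2
    return float(errs.mean())


def ridge_loocv_mse(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Exact LOOCV MSE for ridge via the leverage shortcut.

    For a linear smoother refit on each fold, the held-out residual is
    ``e_i / (1 - h_ii)`` where ``h_ii`` is the leverage of the full-data
    fit (design augmented with an unpenalized intercept column). Agrees
    with :func:`loocv_mse` of :func:`fit_ridge` to round-off but costs one
    solve instead of n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    D = np.eye(p + 1)
    D[0, 0] = 0.0
    M = A.T @ A + alpha * D
    try:
        MinvAt = np.linalg.solve(M, A.T)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"ridge LOOCV system singular: {exc}") from exc
    yhat = A @ (MinvAt @ y)
    h = np.einsum("ij,ji->i", A, MinvAt)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise NumericalError("leverage of 1 encountered; LOOCV undefined")
    loo = (y - yhat) / denom
    return float(np.mean(loo**2))


@dataclass
class GridSearchResult:
    """Outcome of an exhaustive alpha grid search."""

    grid: np.ndarray
    cv_errors: np.ndarray
    best_alpha: float
    best_model: object = None

    def to_dict(self) -> dict:
        return {
            "grid": [float(a) for a in self.grid],
            "cv_errors": [float(e) for e in self.cv_errors],
            "best_alpha": float(self.best_alpha),
        }


def ridge_grid() -> np.ndarray:
    """Ridge alpha grid: 100 down to 0 in steps of 0.1 (1001 points)."""
    return np.round(np.arange(1000, -1, -1) / 10.0, 1)


def ann_grid(coarse: bool = False) -> np.ndarray:
    """ANN alpha grid: 20 down to 0 in steps of 0.1 (201 points).

    ``coarse=True`` returns a 10-point subgrid for routine runs.
    """
    if coarse:
        return np.array([20.0, 15.0, 10.0, 5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.0])
    return np.round(np.arange(200, -1, -1) / 10.0, 1)


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def grid_search_alpha(
    fit_fn: Callable[[np.ndarray, np.ndarray, float], "object"],
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float],
    cv: "str | int" = "loocv",
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid search over the L2 parameter.

    ``fit_fn(X, y, alpha)`` returns a model with ``forward``. ``cv`` is
    ``"loocv"`` or an integer k for k-fold CV (folds fixed by ``seed``;
    squared errors are pooled over all held-out samples). Ties in CV error
    are broken toward the *larger* alpha. The returned result carries the
    final model refit on all rows at the best alpha.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("grid must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    if cv == "loocv":
        folds = [np.array([i]) for i in range(n)]
    else:
        k = int(cv)
        if not 2 <= k <= n:
            raise ParameterError("k-fold cv needs 2 <= k <= n")
        folds = _kfold_indices(n, k, seed)

    cv_errors = np.empty(grid.size)
    for gi, alpha in enumerate(grid):
        sq = np.empty(n)
        for fi, hold in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[hold] = False
            try:
                model = fit_fn(X[mask], y[mask], float(alpha))
            except Exception as exc:  # noqa: BLE001
                raise CrossValidationError(
                    f"fit failed at alpha={alpha} on fold {fi}: {exc}"
                ) from exc
            pred = np.asarray(model.forward(X[hold])).ravel()
            sq[hold] = (pred - y[hold]) ** 2
        cv_errors[gi] = sq.mean()

    best = _argmin_tie_larger_alpha(grid, cv_errors)
    best_alpha = float(grid[best])
    return GridSearchResult(
        grid=grid,
        cv_errors=cv_errors,
        best_alpha=best_alpha,
        best_model=fit_fn(X, y, best_alpha),
    )


def _argmin_tie_larger_alpha(grid: np.ndarray, errors: np.ndarray) -> int:
    best = np.min(errors)
    tied = np.flatnonzero(errors == best)
    return int(tied[np.argmax(grid[tied])])


# ---------------------------------------------------------------------------
# The single-hidden-layer network
# ---------------------------------------------------------------------------


@dataclass
class ANNModel:
    """Single-hidden-layer ReLU perceptron with a square hidden matrix.

    Forward map for a row vector ``x`` of z-scored FA::

        y = ReLU(x @ W + b_h) @ v + c

    ``W[i, j]`` connects input tract i to hidden neuron j.
    """

    W: np.ndarray
    b_h: np.ndarray
    v: np.ndarray
    c: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ParameterError("W must be square")
        if self.b_h.shape != (n,) or self.v.shape != (n,):
            raise ParameterError("b_h and v must have length n")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def hidden_pre(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.W + self.b_h

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predict z-age for rows of z-FA; returns a 1-D array."""
        h = np.maximum(self.hidden_pre(X), 0.0)
        return h @ self.v + self.c

    def copy(self) -> "ANNModel":
        return ANNModel(
            W=self.W.copy(), b_h=self.b_h.copy(), v=self.v.copy(),
            c=float(self.c), alpha=float(self.alpha),
        )

    def n_parameters(self) -> int:
        """Nonzero hidden weights plus all biases and output weights."""
        return int(np.count_nonzero(self.W)) + 2 * self.n + 1

    def to_dict(self) -> dict:
        return {
            "W": [[float(w) for w in row] for row in self.W],
            "b_h": [float(b) for b in self.b_h],
            "v": [float(w) for w in self.v],
            "c": float(self.c),
            "alpha": float(self.alpha),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            b_h=np.asarray(d["b_h"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            c=float(d["c"]),
            alpha=float(d.get("alpha", 0.0)),
        )


def init_ann(ridge: RidgeModel, n: int | None = None) -> ANNModel:
    """Identity-initialized network with a ridge-pretrained output layer.

    ``W = I``, hidden biases 0, output weights = ridge coefficients,
    output bias = ridge intercept. For inputs whose hidden pre-activations
    are all non-negative the initial network equals the ridge model.
    """
    if n is None:
        n = len(ridge.coef)
    if len(ridge.coef) != n:
        raise ParameterError(
            f"ridge has {len(ridge.coef)} coefficients, expected {n}"
        )
    return ANNModel(
        W=np.eye(n),
        b_h=np.zeros(n),
        v=np.asarray(ridge.coef, dtype=float).copy(),
        c=float(ridge.intercept),
        alpha=0.0,
    )


def _loss_and_grads(
    ann: ANNModel, X: np.ndarray, y: np.ndarray, alpha: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, float]:
    """Half-MSE + L2 loss and its gradients w.r.t. (W, b_h, v, c).

    Matches the usual perceptron-regressor convention: the data term is
    ``mean((yhat - y)^2) / 2`` and the penalty ``alpha * (|W|^2 + |v|^2) / (2 n)``
    (biases unpenalized).
    """
    n_s = len(y)
    pre = ann.hidden_pre(X)
    mask = pre > 0
    H = np.where(mask, pre, 0.0)
    yhat = H @ ann.v + ann.c
    err = yhat - y
    loss = 0.5 * float(np.mean(err**2)) + 0.5 * alpha * (
        float(np.sum(ann.W**2)) + float(np.sum(ann.v**2))
    ) / n_s

    base = err / n_s
    dc = float(base.sum())
    dv = H.T @ base + (alpha / n_s) * ann.v
    dH = np.outer(base, ann.v) * mask
    dW = X.T @ dH + (alpha / n_s) * ann.W
    db = dH.sum(axis=0)
    return loss, dW, db, dv, dc


def train_ann(
    ann: ANNModel,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    max_iter: int = 100_000,
    learning_rate: float = 0.001,
    tol: float = 1e-4,
    n_iter_no_change: int = 10,
) -> ANNModel:
    """Full-batch Adam training of the network; input model is not mutated.

    Loss is squared error plus L2 regularization of the weights. Training
    stops when the loss has failed to improve by more than ``tol`` for
    ``n_iter_no_change`` consecutive iterations, or at ``max_iter``
    (default 100,000). With a fixed initialization and full batches the
    procedure is deterministic.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    model = ann.copy()
    model.alpha = float(alpha)
    if max_iter == 0:
        return model

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params = [model.W, model.b_h, model.v, np.array([model.c])]
    m = [np.zeros_like(p) for p in params]
    s = [np.zeros_like(p) for p in params]

    best_loss = np.inf
    no_change = 0
    for t in range(1, max_iter + 1):
        loss, dW, db, dv, dc = _loss_and_grads(model, X, y, alpha)
        if not np.isfinite(loss):
            raise NumericalError(f"training diverged at iteration {t}")
        grads = [dW, db, dv, np.array([dc])]
        for k in range(4):
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            s[k] = beta2 * s[k] + (1 - beta2) * grads[k] ** 2
            mhat = m[k] / (1 - beta1**t)
            shat = s[k] / (1 - beta2**t)
            params[k] -= learning_rate * mhat / (np.sqrt(shat) + eps)
        model.c = float(params[3][0])

        if loss > best_loss - tol:
            no_change += 1
            if no_change >= n_iter_no_change:
                break
        else:
            no_change = 0
        best_loss = min(best_loss, loss)
    return model


def prune_ann(ann: ANNModel, n_train: int) -> ANNModel:
    """Magnitude-prune the hidden matrix to one sample per parameter.

    Repeatedly zeros the smallest-magnitude nonzero entry of ``W`` until
    the total nonzero parameter count (nonzeros of W + both bias vectors +
    output weights + output bias) is at most ``n_train``. Only hidden-matrix
    entries are prunable. If zeroing an entry would make ``W`` numerically
    singular (condition number > 1e8) the entry is restored and pruning
    stops early with a warning.
    """
    model = ann.copy()
    budget = n_train
    while model.n_parameters() > budget:
        nz = np.flatnonzero(model.W)
        if nz.size == 0:
            raise PruningError(
                f"cannot reach parameter budget {budget}; "
                f"{model.n_parameters()} parameters remain with an empty "
                "hidden matrix"
            )
        flat = np.abs(model.W.ravel()[nz])
        victim = nz[np.argmin(flat)]
        i, j = np.unravel_index(victim, model.W.shape)
        saved = model.W[i, j]
        model.W[i, j] = 0.0
        if np.linalg.cond(model.W) > _COND_LIMIT:
            model.W[i, j] = saved
            warnings.warn(
                "pruning stopped early: removing more weights would make the "
                f"hidden matrix singular ({model.n_parameters() - budget} "
                "parameters over budget)",
                RuntimeWarning,
                stacklevel=2,
            )
            break
    return model


# ---------------------------------------------------------------------------
# Prediction in original units
# ---------------------------------------------------------------------------


def predict_age(
    model: "RidgeModel | ANNModel",
    fa: "pd.DataFrame | np.ndarray",
    scaler: Scaler,
) -> np.ndarray:
    """Predict brain age in years from FA values in original units.

    Accepts a cohort table (tract columns selected in canonical order) or a
    raw matrix already ordered canonically.
    """
    if isinstance(fa, pd.DataFrame):
        missing = [t for t in TRACT_NAMES if t not in fa.columns]
        if missing:
            raise ParameterError(f"missing tract columns: {missing}")
    Z = scaler.transform_fa(fa)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != len(scaler.fa_mean):
        raise ParameterError(
            f"expected {len(scaler.fa_mean)} tract columns, got {Z.shape[1]}"
        )
    z_pred = np.asarray(model.forward(Z)).ravel()
    return scaler.invert_age(z_pred)
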