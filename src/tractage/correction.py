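"""Non-linear, interaction-aware age correction by gradient descent on the input.

The trained network is frozen. For one subject with z-scored FA row ``x``:

1. Forward pass gives the predicted brain age ``y``. The correction target
   is ``y_target = y + (global_target_age - chronological_age)`` — the shift
   is applied to the *prediction*, so the subject's brain-age gap is
   preserved rather than erased.
2. The error ``E = y - y_target`` is backpropagated and exactly one plain
   gradient-descent step is taken on the hidden weight matrix, yielding
   ``W' = W - lr * dL/dW`` with ``L = E^2 / 2``.
3. Instead of keeping ``W'``, the *input* is updated:
   ``x <- x @ W' @ W^-1``. A network whose weights had moved to fit the
   target is thereby converted into an input that fits the target under the
   original weights.
4. Constraint rules: if the target age is higher than the chronological age
   FA may only decrease (and vice versa), and the age-invariant cerebellar
   tracts (SCP, MCP) never change. Offending entries are reset to their
   original values each iteration.

Steps 1-4 repeat until ``|E|`` is at most one month (1/12 year). A
tract-wise linear correction (per-tract OLS of FA on age, slope forced to
zero for non-age-dependent tracts) serves as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceError,
    NumericalError,
    ParameterError,
    StallError,
)
from .models import ANNModel
from .preprocessing import Scaler
from .tracts import AGE_INVARIANT_TRACTS, TRACT_NAMES

__all__ = [
    "CorrectionConfig",
    "CorrectionResult",
    "LinearCorrectionModel",
    "correction_target",
    "correction_step",
    "apply_constraints",
    "ann_age_correct",
    "correct_cohort_ann",
    "fit_linear_correction",
    "linear_age_correct",
    "correct_cohort_linear",
]

_COND_LIMIT = 1e8


@dataclass
class CorrectionConfig:
    """Settings for the iterative input correction.

    ``tolerance`` is in years (default one month). ``learning_rate`` is the
    step size of the single transient gradient step, in z-space.
    ``stall_window``/``stall_epsilon`` detect loops that stop improving
    (e.g. every update reverted by the constraints).
    """

    global_target_age: float
    learning_rate: float = 0.001
    tolerance: float = 1.0 / 12.0
    max_iterations: int = 10_000
    frozen_tracts: tuple[str, ...] = AGE_INVARIANT_TRACTS
    stall_window: int = 200
    stall_epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        unknown = set(self.frozen_tracts) - set(TRACT_NAMES)
        if unknown:
            raise ParameterError(f"unknown frozen tracts: {sorted(unknown)}")


@dataclass
class CorrectionResult:
    """Outcome of correcting one subject."""

    corrected_fa: pd.Series
    iterations: int
    final_error: float  # years, signed
    reverted: pd.Series  # per-tract: constraint reversion in last iteration
    y_initial: float  # years
    y_target: float  # years
    y_final: float  # years
    converged: bool = True


def correction_target(
    y_pred: float, chron_age: float, global_target: float
) -> float:
    """Gap-preserving per-subject target: ``y_pred + (global_target - chron)``.

    Shifting the prediction (rather than replacing it by the global target)
    moves every subject by the same amount along the age axis and leaves
    the brain-age gap intact.
    """
    return y_pred + (global_target - chron_age)


def correction_step(
    ann: ANNModel, x: np.ndarray, y_target: float, lr: float = 0.001
) -> np.ndarray:
    """One input-update step in z-space.

    Computes ``E = forward(x) - y_target``, the gradient of ``L = E^2/2``
    with respect to the hidden matrix, the transiently updated matrix
    ``W' = W - lr * dL/dW``, and returns ``x @ W' @ W^-1``. The model is
    not mutated; only ``W`` takes part in the input update.
    """
    x = np.asarray(x, dtype=float).ravel()
    cond = np.linalg.cond(ann.W)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericalError(f"hidden matrix not invertible (cond={cond:.3g})")
    W_inv = np.linalg.inv(ann.W)
    return _step_cached(ann, x, y_target, lr, W_inv)[0]


def _step_cached(
    ann: ANNModel,
    x: np.ndarray,
    y_target: float,
    lr: float,
    W_inv: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Step with a precomputed inverse; returns (x_proposed, E)."""
    pre = x @ ann.W + ann.b_h
    active = pre > 0
    y = float(np.where(active, pre, 0.0) @ ann.v + ann.c)
    E = y - y_target
    if E == 0.0:  # converged point: W' = W, so the input is exactly fixed
        return x.copy(), E
    # dL/dW_ij = E * x_i * v_j * 1[pre_j > 0]
    grad = E * np.outer(x, ann.v * active)
    if not np.all(np.isfinite(grad)):
        raise NumericalError("non-finite gradient in correction step")
    W_prime = ann.W - lr * grad
    return x @ W_prime @ W_inv, E


def apply_constraints(
    x_proposed: np.ndarray,
    x_original: np.ndarray,
    delta_sign: float,
    frozen_indices: "list[int] | np.ndarray",
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce the three correction rules against the *original* input.

    Frozen tracts are always reset. When the target is older than the
    subject (``delta_sign > 0``) FA must not increase; when younger, it
    must not decrease. Returns ``(x_constrained, reverted_flags)``.
    """
    x_proposed = np.asarray(x_proposed, dtype=float).ravel()
    x_original = np.asarray(x_original, dtype=float).ravel()
    if x_proposed.shape != x_original.shape:
        raise ParameterError("proposed and original vectors differ in length")
    reverted = np.zeros(x_proposed.shape, dtype=bool)
    if delta_sign > 0:
        reverted |= x_proposed > x_original
    elif delta_sign < 0:
        reverted |= x_proposed < x_original
    frozen = np.zeros_like(reverted)
    frozen[np.asarray(frozen_indices, dtype=int)] = True
    reverted |= frozen
    out = np.where(reverted, x_original, x_proposed)
    return out, reverted


def ann_age_correct(
    ann: ANNModel,
    scaler: Scaler,
    sample: pd.Series,
    config: CorrectionConfig,
) -> CorrectionResult:
    """Correct one subject's FA vector to the global target age.

    ``sample`` must hold ``age`` and the 21 tract FA values in original
    units. On success the prediction on the corrected input equals the
    subject's target within ``config.tolerance``, frozen tracts are
    bit-identical to the input, and sign constraints hold relative to the
    original values.

    Raises
    ------
    ConvergenceError
        If ``max_iterations`` is reached with ``|E|`` above tolerance.
    StallError
        If ``|E|`` stops improving (all updates reverted or all relevant
        hidden units inactive).
    """
    features = list(scaler.fa_mean.index)
    fa_orig = sample[features].astype(float)
    if fa_orig.isna().any():
        raise ParameterError("sample has missing FA values")
    age = float(sample["age"])

    x0 = scaler.transform_fa(fa_orig.to_numpy()[None, :]).ravel()
    frozen_idx = [
        features.index(t) for t in config.frozen_tracts if t in features
    ]

    cond = np.linalg.cond(ann.W)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericalError(f"hidden matrix not invertible (cond={cond:.3g})")
    W_inv = np.linalg.inv(ann.W)

    y0_z = float(ann.forward(x0)[0])
    y0 = float(scaler.invert_age(y0_z))
    delta = config.global_target_age - age
    y_target_years = correction_target(y0, age, config.global_target_age)
    y_target_z = float(scaler.transform_age(y_target_years))
    tol_z = config.tolerance / scaler.age_sd
    delta_sign = float(np.sign(delta))

    x = x0.copy()
    reverted = np.zeros(len(x0), dtype=bool)
    best_abs_e = np.inf
    stalled_for = 0
    iterations = 0
    E = y0_z - y_target_z
    for it in range(config.max_iterations + 1):
        E = float(ann.forward(x)[0]) - y_target_z
        if abs(E) <= tol_z:
            iterations = it
            break
        if it == config.max_iterations:
            raise ConvergenceError(
                f"no convergence after {config.max_iterations} iterations "
                f"(|E| = {abs(E) * scaler.age_sd:.4f} years)"
            )
        if best_abs_e - abs(E) > config.stall_epsilon:
            best_abs_e = abs(E)
            stalled_for = 0
        else:
            stalled_for += 1
            if stalled_for >= config.stall_window:
                raise StallError(
                    f"no progress over {config.stall_window} iterations "
                    f"(|E| = {abs(E) * scaler.age_sd:.4f} years)"
                )
        x_prop, _ = _step_cached(ann, x, y_target_z, config.learning_rate, W_inv)
        x, reverted = apply_constraints(x_prop, x0, delta_sign, frozen_idx)

    corrected = pd.Series(scaler.invert_fa(x), index=features)
    # entries the constraints pinned to the original z-value get the
    # original FA back verbatim, guaranteeing bit-equality for frozen tracts
    unchanged = x == x0
    corrected[unchanged] = fa_orig[unchanged]

    y_final = float(scaler.invert_age(float(ann.forward(x)[0])))
    return CorrectionResult(
        corrected_fa=corrected,
        iterations=iterations,
        final_error=E * scaler.age_sd,
        reverted=pd.Series(reverted, index=features),
        y_initial=y0,
        y_target=y_target_years,
        y_final=y_final,
    )


def correct_cohort_ann(
    ann: ANNModel,
    scaler: Scaler,
    cohort: pd.DataFrame,
    config: CorrectionConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct every subject; non-convergent subjects are flagged, not fatal.

    Returns ``(corrected, log)``. ``corrected`` has the 21 tract columns
    (NaN for subjects whose correction failed); ``log`` has one row per
    subject with iterations, final error (years), number of reverted
    tracts, predicted/target ages and a ``converged`` flag.
    """
    rows, logs = [], []
    for _, sample in cohort.iterrows():
        try:
            res = ann_age_correct(ann, scaler, sample, config)
            rows.append(res.corrected_fa)
            logs.append(
                {
                    "subject_id": sample.get("subject_id"),
                    "age": float(sample["age"]),
                    "y_initial": res.y_initial,
                    "y_target": res.y_target,
                    "y_final": res.y_final,
                    "iterations": res.iterations,
                    "final_error": res.final_error,
                    "n_reverted": int(res.reverted.sum()),
                    "converged": True,
                }
            )
        except (ConvergenceError, StallError) as exc:
            rows.append(pd.Series(np.nan, index=list(scaler.fa_mean.index)))
            logs.append(
                {
                    "subject_id": sample.get("subject_id"),
                    "age": float(sample["age"]),
                    "y_initial": np.nan,
                    "y_target": np.nan,
                    "y_final": np.nan,
                    "iterations": -1,
                    "final_error": np.nan,
                    "n_reverted": -1,
                    "converged": False,
                    "failure": str(exc),
                }
            )
    corrected = pd.DataFrame(rows).reset_index(drop=True)
    log = pd.DataFrame(logs)
    return corrected, log


# ---------------------------------------------------------------------------
# Tract-wise linear baseline
# ---------------------------------------------------------------------------


@dataclass
class LinearCorrectionModel:
    """Per-tract linear age model ``FA ~ intercept + beta * age``.

    ``beta`` is forced to zero for tracts flagged non-age-dependent, so
    those tracts pass through any correction unchanged.
    """

    beta: pd.Series  # FA units per year
    intercept: pd.Series
    age_dependent: pd.Series


def fit_linear_correction(
    train: pd.DataFrame,
    age_dependent: "dict[str, bool] | None" = None,
) -> LinearCorrectionModel:
    """Per-tract OLS of FA on age over the training set.

    By default every tract is treated as age-dependent except SCP and MCP.
    """
    ages = train["age"].to_numpy(dtype=float)
    if np.std(ages) == 0:
        raise ParameterError("training ages are constant; cannot fit slopes")
    if age_dependent is None:
        age_dependent = {
            t: t not in AGE_INVARIANT_TRACTS for t in TRACT_NAMES
        }
    beta, inter, dep = {}, {}, {}
    for t in TRACT_NAMES:
        fa = train[t].to_numpy(dtype=float)
        dep[t] = bool(age_dependent.get(t, True))
        if dep[t]:
            b, a = np.polyfit(ages, fa, deg=1)
        else:
            b, a = 0.0, float(np.mean(fa))
        beta[t] = float(b)
        inter[t] = float(a)
    idx = list(TRACT_NAMES)
    return LinearCorrectionModel(
        beta=pd.Series(beta)[idx],
        intercept=pd.Series(inter)[idx],
        age_dependent=pd.Series(dep)[idx],
    )


def linear_age_correct(
    model: LinearCorrectionModel,
    sample: pd.Series,
    global_target: float,
) -> pd.Series:
    """Move one subject's FA along the fitted per-tract lines:
    ``FA + beta * (target - age)``."""
    age = float(sample["age"])
    fa = sample[list(TRACT_NAMES)].astype(float)
    return fa + model.beta * (global_target - age)


def correct_cohort_linear(
    model: LinearCorrectionModel,
    cohort: pd.DataFrame,
    global_target: float,
) -> pd.DataFrame:
    """Vectorized :func:`linear_age_correct` over a cohort."""
    shift = np.outer(
        global_target - cohort["age"].to_numpy(dtype=float),
        model.beta.to_numpy(),
    )
    fa = cohort[list(TRACT_NAMES)].to_numpy(dtype=float)
    return pd.DataFrame(fa + shift, columns=list(TRACT_NAMES)).reset_index(
        drop=True
    )
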