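"""Evaluation statistics: R², MAE, bootstrap CIs, normality, Bland-Altman.

The agreement report compares ANN-corrected against linearly corrected FA
values per tract and pooled ("combined"), mirroring the standard
method-comparison layout: R² with bootstrap CI plus Bland-Altman mean
difference and limits of agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MetricError, ParameterError
from .tracts import TRACT_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "r_squared",
    "mae",
    "bootstrap_ci",
    "shapiro_wilk",
    "bland_altman",
    "agreement_report",
    "prediction_report",
]


def r_squared(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Coefficient of determination with ``reference`` defining the variance.

    ``1 - sum((est - ref)^2) / sum((ref - mean(ref))^2)``. May be negative
    when the estimate disagrees with the reference more than a constant
    at the reference mean would.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if reference.size != estimate.size:
        raise ParameterError("reference and estimate differ in length")
    if reference.size < 2:
        raise ParameterError("need at least 2 values")
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("reference has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((estimate - reference) ** 2)) / ss_tot


def mae(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Mean absolute difference."""
    truth = np.asarray(truth, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    if truth.size != estimate.size:
        raise ParameterError("inputs differ in length")
    if truth.size == 0:
        raise ParameterError("empty input")
    return float(np.mean(np.abs(truth - estimate)))


def bootstrap_ci(
    statistic_fn: Callable[..., float],
    paired_data: "Sequence[np.ndarray]",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI over subject-level resamples.

    ``paired_data`` is a sequence of equally long arrays resampled jointly
    (rows = subjects). Returns ``(point, lo, hi)`` with 2.5/97.5 percentile
    bounds. Resamples on which the statistic fails (e.g. zero variance) are
    skipped and counted in the log.
    """
    arrays = [np.asarray(a, dtype=float) for a in paired_data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ParameterError("paired arrays differ in length")
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    point = float(statistic_fn(*arrays))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    values = []
    skipped = 0
    for row in idx:
        try:
            values.append(float(statistic_fn(*(a[row] for a in arrays))))
        except Exception:  # noqa: BLE001 - degenerate resample
            skipped += 1
    if skipped:
        logger.info("bootstrap_ci: skipped %d degenerate resamples", skipped)
    if not values:
        raise MetricError("statistic failed on every bootstrap resample")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return point, float(lo), float(hi)


def shapiro_wilk(errors: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test of prediction errors (3 <= n <= 5000)."""
    errors = np.asarray(errors, dtype=float).ravel()
    if not 3 <= errors.size <= 5000:
        raise ParameterError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(errors)
    return float(res.statistic), float(res.pvalue)


def bland_altman(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Mean difference of ``a - b`` and 1.96-SD limits of agreement."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ParameterError("inputs differ in length")
    if a.size < 2:
        raise ParameterError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    half = 1.96 * float(d.std(ddof=0))
    return mean_diff, mean_diff - half, mean_diff + half


def agreement_report(
    ann_corrected: pd.DataFrame,
    linear_corrected: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tract and combined agreement between the two correction methods.

    The linearly corrected values are the reference for R² (they define
    the denominator variance). The Bland-Altman difference is
    ``linear - ANN``, so a positive mean difference means the ANN produced
    the lower FA. The combined row pools all tract-subject pairs; its
    bootstrap resamples subjects.
    """
    cols = [t for t in TRACT_NAMES if t in ann_corrected.columns]
    if list(linear_corrected[cols].columns) != cols:
        raise ParameterError("corrected tables must share tract columns")
    ann = ann_corrected[cols].to_numpy(dtype=float)
    lin = linear_corrected[cols].to_numpy(dtype=float)
    ok = np.isfinite(ann).all(axis=1) & np.isfinite(lin).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("agreement_report: dropping %d non-convergent subjects", n_dropped)
    ann, lin = ann[ok], lin[ok]

    rows = {}
    for j, t in enumerate(cols):
        r2, r2_lo, r2_hi = bootstrap_ci(
            r_squared, (lin[:, j], ann[:, j]), n_boot=n_boot, seed=seed
        )
        md, lo, hi = bland_altman(lin[:, j], ann[:, j])
        rows[t] = {
            "r2": r2, "r2_lo": r2_lo, "r2_hi": r2_hi,
            "mean_diff": md, "loa_lo": lo, "loa_hi": hi,
        }

    # combined row: resample subjects, then flatten their tract pairs
    def _pooled_r2(subject_idx):
        rows_sel = subject_idx.astype(int)
        return r_squared(lin[rows_sel].ravel(), ann[rows_sel].ravel())

    point = r_squared(lin.ravel(), ann.ravel())
    _, c_lo, c_hi = bootstrap_ci(
        _pooled_r2, (np.arange(len(lin)),), n_boot=n_boot, seed=seed + 1
    )
    md, lo, hi = bland_altman(lin.ravel(), ann.ravel())
    rows["combined"] = {
        "r2": point, "r2_lo": c_lo, "r2_hi": c_hi,
        "mean_diff": md, "loa_lo": lo, "loa_hi": hi,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PredictionReport:
    """R² and MAE with bootstrap CIs, plus error normality."""

    r2: float
    r2_lo: float
    r2_hi: float
    mae: float
    mae_lo: float
    mae_hi: float
    shapiro_w: float
    shapiro_p: float
    n: int

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "r2", "r2_lo", "r2_hi", "mae", "mae_lo", "mae_hi",
            "shapiro_w", "shapiro_p",
        )} | {"n": int(self.n)}


def prediction_report(
    age_true: np.ndarray,
    age_pred: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionReport:
    """Summarize prediction accuracy on one data set (chronological age as
    reference)."""
    age_true = np.asarray(age_true, dtype=float).ravel()
    age_pred = np.asarray(age_pred, dtype=float).ravel()
    r2, r2_lo, r2_hi = bootstrap_ci(
        r_squared, (age_true, age_pred), n_boot=n_boot, seed=seed
    )
    m, m_lo, m_hi = bootstrap_ci(
        mae, (age_true, age_pred), n_boot=n_boot, seed=seed + 1
    )
    w, p = shapiro_wilk(age_true - age_pred)
    return PredictionReport(
        r2=r2, r2_lo=r2_lo, r2_hi=r2_hi,
        mae=m, mae_lo=m_lo, mae_hi=m_hi,
        shapiro_w=w, shapiro_p=p, n=len(age_true),
    )
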