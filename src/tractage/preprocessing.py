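"""Sample filtering, train/test split, z-space calibration, harmonization.

All model mathematics happens in z-space: tract FA columns and the age
target are standardized with means and SDs estimated on the *training*
rows only. Centering the target makes the ridge intercept exactly zero,
which is also what anchors the identity-initialized network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScalerError,
    EmptyCohortError,
    HarmonizationError,
    ParameterError,
)
from .tracts import TRACT_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Scaler",
    "SplitResult",
    "drop_incomplete",
    "split_cohort",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "harmonize_protocols",
]


def drop_incomplete(cohort: pd.DataFrame) -> pd.DataFrame:
    """Remove subjects with any missing tract FA value.

    A row missing several values still counts as one discarded subject.
    """
    mask = cohort[list(TRACT_NAMES)].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("drop_incomplete: discarded %d of %d rows", n_dropped, len(cohort))
    out = cohort.loc[mask].reset_index(drop=True)
    if out.empty:
        raise EmptyCohortError("all rows had missing FA values")
    return out


@dataclass
class SplitResult:
    """A reproducible 80:20 (by default) train/test partition."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int


def split_cohort(
    cohort: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Uniformly random partition into train and test.

    Test size is ``floor(test_fraction * n)``; with n = 217 and the default
    fraction this yields 43 test and 174 training subjects.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError("test_fraction must be in (0, 1)")
    n = len(cohort)
    if n < 5:
        raise ParameterError("need at least 5 subjects to split")
    n_test = int(np.floor(test_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return SplitResult(
        train=cohort.iloc[train_idx].reset_index(drop=True),
        test=cohort.iloc[test_idx].reset_index(drop=True),
        seed=seed,
    )


@dataclass
class Scaler:
    """Training-set standardization parameters for FA columns and age.

    SDs are population SDs (ddof = 0). All fields are fitted exclusively on
    training rows; test data are transformed with the training statistics.
    """

    fa_mean: pd.Series
    fa_sd: pd.Series
    age_mean: float
    age_sd: float

    # -- array-level transforms -------------------------------------------
    def transform_fa(self, fa: pd.DataFrame | np.ndarray) -> np.ndarray:
        """FA (original units) -> z-space matrix, canonical tract order."""
        if isinstance(fa, pd.DataFrame):
            fa = fa[list(TRACT_NAMES)].to_numpy(dtype=float)
        else:
            fa = np.asarray(fa, dtype=float)
        return (fa - self.fa_mean.to_numpy()) / self.fa_sd.to_numpy()

    def invert_fa(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.fa_sd.to_numpy() + self.fa_mean.to_numpy()

    def transform_age(self, age):
        return (np.asarray(age, dtype=float) - self.age_mean) / self.age_sd

    def invert_age(self, z):
        return np.asarray(z, dtype=float) * self.age_sd + self.age_mean

    def to_dict(self) -> dict:
        return {
            "fa_mean": {t: float(self.fa_mean[t]) for t in TRACT_NAMES},
            "fa_sd": {t: float(self.fa_sd[t]) for t in TRACT_NAMES},
            "age_mean": float(self.age_mean),
            "age_sd": float(self.age_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            fa_mean=pd.Series({t: d["fa_mean"][t] for t in TRACT_NAMES}),
            fa_sd=pd.Series({t: d["fa_sd"][t] for t in TRACT_NAMES}),
            age_mean=float(d["age_mean"]),
            age_sd=float(d["age_sd"]),
        )


def fit_scaler(train: pd.DataFrame) -> Scaler:
    """Estimate per-tract FA and age standardization from training rows."""
    fa = train[list(TRACT_NAMES)]
    if fa.isna().any().any():
        raise ParameterError("training set must be complete; run drop_incomplete")
    fa_mean = fa.mean()
    fa_sd = fa.std(ddof=0)
    age = train["age"].to_numpy(dtype=float)
    age_sd = float(np.std(age))
    bad = fa_sd[fa_sd <= 0]
    if len(bad) or age_sd <= 0:
        names = list(bad.index) + (["age"] if age_sd <= 0 else [])
        raise DegenerateScalerError(f"zero variance in training columns: {names}")
    return Scaler(
        fa_mean=fa_mean, fa_sd=fa_sd, age_mean=float(np.mean(age)), age_sd=age_sd
    )


def apply_scaler(scaler: Scaler, cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with tract FA and age replaced by their z-scores."""
    out = cohort.copy()
    out[list(TRACT_NAMES)] = scaler.transform_fa(cohort)
    out["age"] = scaler.transform_age(cohort["age"].to_numpy())
    return out


def invert_scaler(scaler: Scaler, zcohort: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`apply_scaler` (identity to round-off)."""
    out = zcohort.copy()
    out[list(TRACT_NAMES)] = scaler.invert_fa(
        zcohort[list(TRACT_NAMES)].to_numpy(dtype=float)
    )
    out["age"] = scaler.invert_age(zcohort["age"].to_numpy())
    return out


def harmonize_protocols(
    cohort: pd.DataFrame,
    reference_protocol: str,
    age_bin_width: float = 10.0,
) -> pd.DataFrame:
    """Tract-level analog of protocol harmonization.

    For each non-reference protocol and each tract, the mean FA difference
    (protocol minus reference) is computed within age bins that contain
    subjects from both protocols, averaged over those bins, and subtracted
    from the protocol's rows. Reference rows are returned unchanged. This
    is a deliberate tract-level adaptation of voxel-wise difference-map
    harmonization, which needs imaging data the package does not consume.
    """
    if "protocol" not in cohort.columns:
        raise ParameterError("cohort has no 'protocol' column")
    protos = cohort["protocol"].dropna().unique()
    if reference_protocol not in protos:
        raise ParameterError(f"reference protocol {reference_protocol!r} not present")
    if len(protos) < 2:
        return cohort.copy()

    out = cohort.copy()
    bins = np.floor(cohort["age"].to_numpy() / age_bin_width).astype(int)
    ref_mask = (cohort["protocol"] == reference_protocol).to_numpy()
    for proto in protos:
        if proto == reference_protocol:
            continue
        p_mask = (cohort["protocol"] == proto).to_numpy()
        shared = sorted(set(bins[ref_mask]) & set(bins[p_mask]))
        if not shared:
            raise HarmonizationError(
                f"protocols {proto!r} and {reference_protocol!r} share no age bins"
            )
        for t in TRACT_NAMES:
            col = cohort[t].to_numpy(dtype=float)
            diffs = [
                np.nanmean(col[p_mask & (bins == b)])
                - np.nanmean(col[ref_mask & (bins == b)])
                for b in shared
            ]
            out.loc[p_mask, t] = col[p_mask] - float(np.mean(diffs))
    return out
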