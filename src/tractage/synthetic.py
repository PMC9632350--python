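"""Synthetic cohort generator.

Real tract-FA cohorts are rarely shareable, so the package ships a
generator that emulates the age structure the brain-age model assumes:
per tract, mean FA is flat until a tract-specific onset age and then
declines linearly, with Gaussian measurement noise. Two cerebellar tracts
(SCP, MCP) are age-invariant. Each subject additionally carries a latent
"brain-age gap" shift delta that moves their effective age in *every*
tract, so that the generator has a well-defined, gap-preserving ground
truth for age correction (:func:`oracle_corrected_fa`).

Generating model, per subject i and tract t::

    FA_t(i) = baseline_t - slope_t * max(0, age_i + delta_i - onset_t)
              + protocol_offset_t + eps,   eps ~ N(0, noise_sd_t),
              delta_i ~ N(0, gap_sd)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .tracts import AGE_INVARIANT_TRACTS, N_TRACTS, TRACT_NAMES

__all__ = [
    "TractParams",
    "GeneratorConfig",
    "default_tract_params",
    "generate_cohort",
    "oracle_corrected_fa",
    "inject_missing",
]


@dataclass(frozen=True)
class TractParams:
    """Aging parameters for one tract.

    Parameters
    ----------
    name:
        One of the 21 canonical tract identifiers.
    baseline_fa:
        Mean FA before decline onset (dimensionless, in (0.2, 0.8)).
    onset_age:
        Age in years at which linear decline begins.
    slope:
        FA units lost per year after onset (>= 0).
    noise_sd:
        SD of additive Gaussian measurement noise, FA units (>= 0).
    """

    name: str
    baseline_fa: float
    onset_age: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.name not in TRACT_NAMES:
            raise ParameterError(f"unknown tract name {self.name!r}")
        if not (0.2 < self.baseline_fa < 0.8):
            raise ParameterError(
                f"{self.name}: baseline_fa {self.baseline_fa} outside (0.2, 0.8)"
            )
        if self.slope < 0:
            raise ParameterError(f"{self.name}: slope must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError(f"{self.name}: noise_sd must be >= 0")


# Fixed default aging parameters: baselines 0.35-0.60, decline onsets
# 30-50 y, slopes 0.0005-0.0020 FA/y, noise SD 0.010-0.030 — the regime in
# which healthy-adult tract FA is usually reported. SCP and MCP have zero
# slope (no age-associated change).
_DEFAULT_TABLE: tuple[tuple[str, float, float, float, float], ...] = (
    ("CST", 0.54, 34.0, 0.0009, 0.014),
    ("Frontooccipital", 0.43, 38.0, 0.0012, 0.018),
    ("Uncinate", 0.40, 33.0, 0.0010, 0.016),
    ("OpticRadiation", 0.48, 42.0, 0.0014, 0.022),
    ("SLF", 0.45, 36.0, 0.0011, 0.015),
    ("ILF", 0.46, 40.0, 0.0013, 0.020),
    ("Cingulum", 0.50, 31.0, 0.0008, 0.017),
    ("SCP", 0.58, 40.0, 0.0, 0.012),
    ("MCP", 0.56, 40.0, 0.0, 0.011),
    ("Corticostriatal", 0.42, 30.0, 0.0018, 0.013),
    ("Corticopontine", 0.52, 35.0, 0.0010, 0.014),
    ("Corticorubral", 0.47, 30.0, 0.0020, 0.012),
    ("PerforantPath", 0.36, 37.0, 0.0007, 0.024),
    ("TempHypothalamus", 0.38, 44.0, 0.0006, 0.026),
    ("AIC", 0.49, 39.0, 0.0009, 0.019),
    ("PIC", 0.57, 46.0, 0.0005, 0.013),
    ("CC_I", 0.44, 32.0, 0.0016, 0.021),
    ("CC_II", 0.46, 34.0, 0.0015, 0.020),
    ("CC_III", 0.50, 36.0, 0.0013, 0.018),
    ("CC_IV", 0.48, 41.0, 0.0012, 0.023),
    ("CC_V", 0.52, 45.0, 0.0011, 0.019),
)


def default_tract_params(noise_sd: float | None = None) -> tuple[TractParams, ...]:
    """The default 21-tract parameter set.

    Parameters
    ----------
    noise_sd:
        If given, overrides every tract's noise SD (useful for low-noise
        validation cohorts); otherwise the per-tract defaults apply.
    """
    return tuple(
        TractParams(name, b, o, s, noise_sd if noise_sd is not None else n)
        for name, b, o, s, n in _DEFAULT_TABLE
    )


@dataclass
class GeneratorConfig:
    """Configuration of :func:`generate_cohort`.

    ``gap_sd`` is the SD (years) of the subject-level latent age shift
    delta — the synthetic "brain-age gap". ``protocol_offsets`` maps a
    protocol label to per-tract additive FA offsets (a mapping
    tract name -> offset); subjects are assigned protocols uniformly at
    random when offsets are provided.
    """

    n_subjects: int = 217
    age_min: float = 20.0
    age_max: float = 82.0
    tract_params: tuple[TractParams, ...] = field(default_factory=default_tract_params)
    gap_sd: float = 5.0
    protocol_offsets: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if not self.age_min < self.age_max:
            raise ParameterError("age_min must be < age_max")
        self.tract_params = tuple(self.tract_params)
        if len(self.tract_params) != N_TRACTS:
            raise ParameterError(f"need exactly {N_TRACTS} tract_params")
        names = [p.name for p in self.tract_params]
        if len(set(names)) != N_TRACTS:
            raise ParameterError("tract_params names must be unique")
        if self.gap_sd < 0:
            raise ParameterError("gap_sd must be >= 0")
        if self.protocol_offsets is not None:
            for proto, offs in self.protocol_offsets.items():
                unknown = set(offs) - set(TRACT_NAMES)
                if unknown:
                    raise ParameterError(
                        f"protocol {proto!r}: unknown tracts {sorted(unknown)}"
                    )

    def params_by_name(self) -> dict[str, TractParams]:
        return {p.name: p for p in self.tract_params}


def _expected_fa(
    params: TractParams, age_plus_gap: np.ndarray
) -> np.ndarray:
    """Noise-free FA under the piecewise-linear aging model."""
    return params.baseline_fa - params.slope * np.maximum(
        0.0, age_plus_gap - params.onset_age
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort.

    Returns a table with columns ``subject_id``, ``age``, ``sex``,
    optionally ``protocol``, the 21 tract FA columns in canonical order,
    and ``true_gap`` (the latent shift delta, recorded so that the
    age-correction oracle can be evaluated). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ages = rng.uniform(config.age_min, config.age_max, size=n)
    gap = rng.normal(0.0, config.gap_sd, size=n) if config.gap_sd > 0 else np.zeros(n)
    sex = rng.choice(["F", "M"], size=n)

    data: dict[str, object] = {
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": ages,
        "sex": sex,
    }

    offsets_per_subject: dict[str, np.ndarray] = {}
    if config.protocol_offsets:
        protos = sorted(config.protocol_offsets)
        assigned = rng.choice(protos, size=n)
        data["protocol"] = assigned
        for t in TRACT_NAMES:
            off = np.array(
                [config.protocol_offsets[p].get(t, 0.0) for p in assigned]
            )
            offsets_per_subject[t] = off

    by_name = config.params_by_name()
    eff_age = ages + gap
    for t in TRACT_NAMES:
        p = by_name[t]
        fa = _expected_fa(p, eff_age)
        if t in offsets_per_subject:
            fa = fa + offsets_per_subject[t]
        if p.noise_sd > 0:
            fa = fa + rng.normal(0.0, p.noise_sd, size=n)
        data[t] = fa

    data["true_gap"] = gap
    return pd.DataFrame(data)


def oracle_corrected_fa(
    cohort: pd.DataFrame, target_age: float, config: GeneratorConfig
) -> pd.DataFrame:
    """Ground-truth age-corrected FA for a generated cohort.

    Moves each subject's systematic age effect to ``target_age`` while
    preserving both the measurement noise and the latent gap delta::

        FA_corr = FA_obs + slope_t * (max(0, age + delta - onset_t)
                                      - max(0, target + delta - onset_t))

    This mirrors a gap-preserving correction: a subject whose tracts look
    older than their chronological age stays equally "old-looking" at the
    target age.

    Raises
    ------
    ContractError
        If the cohort lacks the ``true_gap`` column (i.e. was not produced
        by :func:`generate_cohort`).
    """
    if "true_gap" not in cohort.columns:
        raise ContractError("cohort has no 'true_gap' column; oracle undefined")
    by_name = config.params_by_name()
    eff_age = cohort["age"].to_numpy() + cohort["true_gap"].to_numpy()
    eff_target = target_age + cohort["true_gap"].to_numpy()
    out = {}
    for t in TRACT_NAMES:
        p = by_name[t]
        shift = p.slope * (
            np.maximum(0.0, eff_age - p.onset_age)
            - np.maximum(0.0, eff_target - p.onset_age)
        )
        out[t] = cohort[t].to_numpy() + shift
    return pd.DataFrame(out, index=cohort.index)


def inject_missing(
    cohort: pd.DataFrame, fraction: float, seed: int
) -> pd.DataFrame:
    """Blank one random tract FA cell in a random ``fraction`` of rows.

    Exercises the incomplete-sample path without altering the remaining
    rows. Returns a copy.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n_rows = int(np.floor(fraction * len(out)))
    if n_rows == 0:
        return out
    rows = rng.choice(len(out), size=n_rows, replace=False)
    cols = rng.choice(list(TRACT_NAMES), size=n_rows)
    for r, c in zip(rows, cols):
        out.iloc[r, out.columns.get_loc(c)] = np.nan
    return out
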