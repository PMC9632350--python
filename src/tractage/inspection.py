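"""Model inspection: permutation importance and hidden-matrix structure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MetricError, ParameterError
from .tracts import TRACT_NAMES

__all__ = [
    "ImportanceReport",
    "permutation_importance",
    "diagonal_dominant",
    "convergent_neurons",
]


@dataclass
class ImportanceReport:
    """Per-tract mean and SD of the R-squared drop under column permutation.

    Negative mean importances are retained; ``display_values`` offers the
    common presentation variant where negatives are clipped to zero.
    """

    importance: pd.DataFrame  # columns: mean, sd; index: tract names
    n_repeats: int
    seed: int
    baseline_score: float

    def display_values(self) -> pd.Series:
        """Mean importances with negatives set to 0 (presentation only)."""
        return self.importance["mean"].clip(lower=0.0)

    def to_frame(self) -> pd.DataFrame:
        return self.importance.copy()


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum((pred - y) ** 2)) / ss_tot


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 1000,
    seed: int = 0,
    feature_names: "tuple[str, ...]" = TRACT_NAMES,
) -> ImportanceReport:
    """Permutation feature importance on an evaluation set.

    For each feature, the drop in R-squared when that column is shuffled
    within the evaluation set, averaged over ``n_repeats`` shuffles. The
    baseline score is computed once. ``model`` needs a ``forward`` method;
    X and y must be in the space the model consumes (R-squared is invariant
    under the affine z-transform, so z-space and years give identical
    importances).
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ParameterError("need at least 3 evaluation samples")
    if np.std(y) == 0:
        raise MetricError("evaluation target has zero variance")
    if X.shape[1] != len(feature_names):
        raise ParameterError("feature_names length does not match X")

    rng = np.random.default_rng(seed)
    baseline = _r2(y, np.asarray(model.forward(X)).ravel())
    means = np.empty(X.shape[1])
    sds = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        drops = np.empty(n_repeats)
        Xp = X.copy()
        for r in range(n_repeats):
            Xp[:, j] = X[rng.permutation(len(y)), j]
            drops[r] = baseline - _r2(y, np.asarray(model.forward(Xp)).ravel())
        means[j] = drops.mean()
        sds[j] = drops.std(ddof=1) if n_repeats > 1 else 0.0
    frame = pd.DataFrame(
        {"mean": means, "sd": sds}, index=list(feature_names)
    )
    return ImportanceReport(
        importance=frame, n_repeats=n_repeats, seed=seed, baseline_score=baseline
    )


def diagonal_dominant(ann) -> pd.Series:
    """Per hidden neuron: does its own tract carry the highest incoming weight?

    Neuron j is diagonally dominant iff ``W[j, j] == max_i W[i, j]``
    (highest signed value in column j).
    """
    W = ann.W
    col_max = W.max(axis=0)
    flags = np.diag(W) >= col_max
    names = list(TRACT_NAMES[: ann.n]) if ann.n <= len(TRACT_NAMES) else list(
        range(ann.n)
    )
    return pd.Series(flags, index=names)


def convergent_neurons(ann, threshold: int = 10) -> pd.DataFrame:
    """Hidden neurons on which many input tracts converge.

    Returns neurons whose column of ``W`` holds at least ``threshold``
    nonzero incoming weights (boundary inclusive), each labeled by the
    input tract contributing its largest weight.
    """
    W = ann.W
    names = list(TRACT_NAMES[: ann.n]) if ann.n <= len(TRACT_NAMES) else [
        str(i) for i in range(ann.n)
    ]
    records = []
    for j in range(ann.n):
        count = int(np.count_nonzero(W[:, j]))
        if count >= threshold:
            records.append(
                {
                    "neuron": j,
                    "neuron_tract": names[j],
                    "n_incoming": count,
                    "largest_weight_tract": names[int(np.argmax(W[:, j]))],
                }
            )
    return pd.DataFrame(
        records, columns=["neuron", "neuron_tract", "n_incoming", "largest_weight_tract"]
    )
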