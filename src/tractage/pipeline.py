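"""End-to-end orchestration: split → scale → ridge → network → prune.

The pipeline reproduces the full model-construction procedure and hands
back one object that can predict, inspect and age-correct. Two speeds:

* ``fast=True`` (default): full ridge grid (100→0, step 0.1, exact LOOCV
  via the leverage shortcut) but a 10-point network grid with k-fold CV —
  the routine desk-scale mode.
* ``fast=False``: the exhaustive 201-point network grid with LOOCV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import (
    CorrectionConfig,
    correct_cohort_ann,
    correct_cohort_linear,
    fit_linear_correction,
    LinearCorrectionModel,
)
from .evaluation import agreement_report, prediction_report, PredictionReport
from .models import (
    ANNModel,
    GridSearchResult,
    RidgeModel,
    ann_grid,
    fit_ridge,
    grid_search_alpha,
    init_ann,
    predict_age,
    prune_ann,
    ridge_grid,
    ridge_loocv_mse,
    train_ann,
    _argmin_tie_larger_alpha,
)
from .preprocessing import (
    Scaler,
    SplitResult,
    apply_scaler,
    drop_incomplete,
    fit_scaler,
    split_cohort,
)
from .tracts import TRACT_NAMES

__all__ = ["TrainedPipeline", "train_pipeline"]


@dataclass
class TrainedPipeline:
    """A fitted brain-age pipeline."""

    scaler: Scaler
    ridge: RidgeModel
    ridge_search: GridSearchResult
    ann: ANNModel
    ann_search: GridSearchResult
    split: SplitResult
    seed: int
    fast: bool

    # -- prediction -------------------------------------------------------
    def predict(self, cohort: pd.DataFrame, model: str = "ann") -> np.ndarray:
        """Brain age in years; ``model`` is ``"ann"`` or ``"ridge"``."""
        m = self.ann if model == "ann" else self.ridge
        return predict_age(m, cohort, self.scaler)

    def evaluate(
        self, cohort: "pd.DataFrame | None" = None, model: str = "ann",
        n_boot: int = 1000, seed: int = 0,
    ) -> PredictionReport:
        """Prediction report (default: on the held-out test set)."""
        data = self.split.test if cohort is None else cohort
        pred = self.predict(data, model=model)
        return prediction_report(
            data["age"].to_numpy(dtype=float), pred, n_boot=n_boot, seed=seed
        )

    # -- correction -------------------------------------------------------
    def test_mean_age(self) -> float:
        return float(self.split.test["age"].mean())

    def correct_test_set(
        self,
        global_target: "float | None" = None,
        config: "CorrectionConfig | None" = None,
    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """ANN- and linear-correct all test subjects to the global target age.

        Default target is the test-set mean chronological age. Returns
        ``(ann_corrected, linear_corrected, log)``.
        """
        if global_target is None:
            global_target = self.test_mean_age()
        if config is None:
            config = CorrectionConfig(global_target_age=global_target)
        ann_fa, log = correct_cohort_ann(
            self.ann, self.scaler, self.split.test, config
        )
        linear_model = self.linear_correction_model()
        lin_fa = correct_cohort_linear(linear_model, self.split.test, global_target)
        return ann_fa, lin_fa, log

    def linear_correction_model(self) -> LinearCorrectionModel:
        return fit_linear_correction(self.split.train)

    def agreement(
        self, n_boot: int = 1000, seed: int = 0,
        global_target: "float | None" = None,
    ) -> pd.DataFrame:
        """Table of per-tract and combined agreement between both corrections."""
        ann_fa, lin_fa, _ = self.correct_test_set(global_target=global_target)
        return agreement_report(ann_fa, lin_fa, n_boot=n_boot, seed=seed)

    # -- z-space views ----------------------------------------------------
    def test_z(self) -> tuple[np.ndarray, np.ndarray]:
        z = apply_scaler(self.scaler, self.split.test)
        return (
            z[list(TRACT_NAMES)].to_numpy(dtype=float),
            z["age"].to_numpy(dtype=float),
        )


def _ridge_grid_search(X: np.ndarray, y: np.ndarray) -> GridSearchResult:
    """Exhaustive ridge grid with the exact-LOOCV leverage shortcut."""
    grid = ridge_grid()
    errors = np.array([ridge_loocv_mse(X, y, a) for a in grid])
    best = _argmin_tie_larger_alpha(grid, errors)
    best_alpha = float(grid[best])
    return GridSearchResult(
        grid=grid,
        cv_errors=errors,
        best_alpha=best_alpha,
        best_model=fit_ridge(X, y, best_alpha),
    )


def train_pipeline(
    cohort: pd.DataFrame,
    seed: int = 0,
    fast: bool = True,
    test_fraction: float = 0.2,
    ann_cv_folds: int = 5,
    ann_max_iter: int = 100_000,
    ann_cv_max_iter: int = 3000,
) -> TrainedPipeline:
    """Run the full model-construction procedure on a cohort.

    Steps: drop incomplete rows, random 80:20 split (``seed``), fit the
    z-scaler on training rows, exhaustive ridge alpha grid (LOOCV),
    identity-initialize the network from the ridge solution, network alpha
    grid (LOOCV, or k-fold in fast mode; every fold re-pretrains its own
    ridge output layer), train the final network on the whole training
    set, then magnitude-prune to one parameter per training sample.
    """
    cohort = drop_incomplete(cohort)
    split = split_cohort(cohort, test_fraction=test_fraction, seed=seed)
    scaler = fit_scaler(split.train)
    z_train = apply_scaler(scaler, split.train)
    X = z_train[list(TRACT_NAMES)].to_numpy(dtype=float)
    y = z_train["age"].to_numpy(dtype=float)

    ridge_search = _ridge_grid_search(X, y)
    ridge = ridge_search.best_model

    def fit_ann_at(Xf: np.ndarray, yf: np.ndarray, alpha: float) -> ANNModel:
        # per-fold pretraining: the output layer restarts from the ridge
        # solution of that fold's training rows
        fold_ridge = fit_ridge(Xf, yf, ridge_search.best_alpha)
        ann0 = init_ann(fold_ridge)
        return train_ann(
            ann0, Xf, yf, alpha,
            max_iter=ann_cv_max_iter if fast else ann_max_iter,
        )

    ann_search = grid_search_alpha(
        fit_ann_at, X, y,
        grid=ann_grid(coarse=fast),
        cv=ann_cv_folds if fast else "loocv",
        seed=seed,
    )
    ann0 = init_ann(ridge)
    ann_trained = train_ann(
        ann0, X, y, ann_search.best_alpha, max_iter=ann_max_iter
    )
    ann_pruned = prune_ann(ann_trained, n_train=len(split.train))
    ann_search.best_model = ann_pruned

    return TrainedPipeline(
        scaler=scaler,
        ridge=ridge,
        ridge_search=ridge_search,
        ann=ann_pruned,
        ann_search=ann_search,
        split=split,
        seed=seed,
        fast=fast,
    )
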