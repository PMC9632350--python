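"""File formats and persistence.

Cohorts travel as CSV/TSV with the canonical 21-tract header; trained
models (scaler + ridge + network + metadata) persist as a single JSON
document with explicit zeros in the pruned hidden matrix; run
configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, SchemaError
from .models import ANNModel, RidgeModel
from .preprocessing import Scaler
from .tracts import TRACT_NAMES

__all__ = [
    "read_cohort",
    "write_cohort",
    "ModelBundle",
    "save_model",
    "load_model",
    "RunConfig",
]

MODEL_FORMAT_VERSION = 1

_REQUIRED = ("subject_id", "age") + TRACT_NAMES
_OPTIONAL_ORDER = ("sex", "protocol")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_cohort(path: "str | Path") -> pd.DataFrame:
    """Read a cohort table from CSV/TSV.

    Required columns: ``subject_id``, ``age`` and the 21 tract names;
    ``sex``, ``protocol`` and ``true_gap`` are optional, unknown columns
    pass through. Empty cells and the usual NA spellings become missing FA
    values (removable via :func:`~tractage.preprocessing.drop_incomplete`).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"subject_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[age.isna() & df["age"].notna()]
    if len(bad):
        raise SchemaError(f"non-numeric age in row {int(bad[0]) + 2} of {path.name}")
    df["age"] = age
    for t in TRACT_NAMES:
        df[t] = pd.to_numeric(df[t], errors="coerce")
    return df


def write_cohort(cohort: pd.DataFrame, path: "str | Path") -> None:
    """Write a cohort with the canonical column ordering."""
    path = Path(path)
    lead = ["subject_id", "age"] + [c for c in _OPTIONAL_ORDER if c in cohort.columns]
    cols = lead + list(TRACT_NAMES)
    if "true_gap" in cohort.columns:
        cols.append("true_gap")
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")


@dataclass
class ModelBundle:
    """Everything needed to predict and correct: scaler + both models."""

    scaler: Scaler
    ridge: RidgeModel
    ann: ANNModel
    metadata: dict = field(default_factory=dict)


def save_model(bundle: ModelBundle, path: "str | Path") -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "scaler": bundle.scaler.to_dict(),
        "ridge": bundle.ridge.to_dict(),
        "ann": bundle.ann.to_dict(),
        "metadata": bundle.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: "str | Path") -> ModelBundle:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"model file {path} is not valid JSON: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return ModelBundle(
        scaler=Scaler.from_dict(doc["scaler"]),
        ridge=RidgeModel.from_dict(doc["ridge"]),
        ann=ANNModel.from_dict(doc["ann"]),
        metadata=doc.get("metadata", {}),
    )


@dataclass
class RunConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    n_subjects: int = 217
    generator_seed: int = 0
    gap_sd: float = 5.0
    noise_sd: "float | None" = None  # None = per-tract defaults
    split_seed: int = 0
    test_fraction: float = 0.2
    fast: bool = True  # coarse ANN grid + k-fold CV instead of full LOOCV
    ann_cv_folds: int = 5
    ann_max_iter: int = 100_000
    correction_learning_rate: float = 0.001
    correction_tolerance: float = 1.0 / 12.0
    correction_max_iterations: int = 10_000
    n_boot: int = 1000
    bootstrap_seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
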