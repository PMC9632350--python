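"""Canonical white-matter tract systems.

The model works on mean fractional anisotropy (FA) of 21 named tracts of
interest. The column order below is canonical: every table, matrix and
report in the package uses it, so that weight-matrix row/column *i* always
refers to the same tract.
"""

from __future__ import annotations

# Short machine-friendly identifiers (CSV column names), canonical order.
TRACT_NAMES: tuple[str, ...] = (
    "CST",
    "Frontooccipital",
    "Uncinate",
    "OpticRadiation",
    "SLF",
    "ILF",
    "Cingulum",
    "SCP",
    "MCP",
    "Corticostriatal",
    "Corticopontine",
    "Corticorubral",
    "PerforantPath",
    "TempHypothalamus",
    "AIC",
    "PIC",
    "CC_I",
    "CC_II",
    "CC_III",
    "CC_IV",
    "CC_V",
)

N_TRACTS: int = len(TRACT_NAMES)

# Human-readable labels for reports and plots.
TRACT_LABELS: dict[str, str] = {
    "CST": "Corticospinal tract",
    "Frontooccipital": "Frontooccipital tract",
    "Uncinate": "Fasciculus uncinatus",
    "OpticRadiation": "Optic radiation",
    "SLF": "Superior longitudinal fasciculus",
    "ILF": "Inferior longitudinal fasciculus",
    "Cingulum": "Cingulum",
    "SCP": "Superior cerebellar peduncle",
    "MCP": "Middle cerebellar peduncle",
    "Corticostriatal": "Corticostriatal tract",
    "Corticopontine": "Corticopontine tract",
    "Corticorubral": "Corticorubral tract",
    "PerforantPath": "Perforant path",
    "TempHypothalamus": "Temporal lobe to hypothalamus",
    "AIC": "Anterior limb of internal capsule",
    "PIC": "Posterior limb of internal capsule",
    "CC_I": "CC I associated tracts",
    "CC_II": "CC II associated tracts",
    "CC_III": "CC III associated tracts",
    "CC_IV": "CC IV associated tracts",
    "CC_V": "CC V associated tracts",
}

# Cerebellar tracts without age-associated FA change; held fixed during
# age correction and given zero slope in the linear baseline.
AGE_INVARIANT_TRACTS: tuple[str, ...] = ("SCP", "MCP")


def tract_indices(names: "list[str] | tuple[str, ...]") -> list[int]:
    """Map tract names to their positions in the canonical order."""
    pos = {t: i for i, t in enumerate(TRACT_NAMES)}
    missing = [n for n in names if n not in pos]
    if missing:
        from .errors import ParameterError

        raise ParameterError(f"unknown tract name(s): {missing}")
    return [pos[n] for n in names]
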