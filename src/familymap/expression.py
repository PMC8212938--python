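"""Stress-expression utilities: Livak qPCR quantification and TPM filters.

Relative expression follows the comparative threshold-cycle (2^-ddCt) method:
dCt = Ct(target) - Ct(reference), ddCt = dCt(treated) - dCt(control), and the
fold change is 2**(-ddCt).  TPM matrices are log2-transformed with a
pseudocount for display, and genes are classed by how many of the four
abiotic stresses (cold, drought, heat, PEG/osmotic) they are detected under.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "STRESSES",
    "relative_expression",
    "qpcr_fold_changes",
    "log2_transform",
    "stress_response_filter",
]

STRESSES = ("cold", "drought", "heat", "PEG")
DEFAULT_DETECT_THRESHOLD = 0.5


class ExpressionError(ValueError):
    """Raised for invalid expression inputs."""


@dataclass
class CtRecord:
    """One qPCR measurement: target and endogenous-reference cycle values."""

    gene: str
    sample: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ExpressionError(
                    f"cycle values must be finite and positive (gene {self.gene!r})"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression(treated: CtRecord, control: CtRecord) -> float:
    """Fold change 2^-ddCt of ``treated`` relative to ``control``; 1.0 means
    no change.  Both records must measure the same gene."""
    if treated.gene != control.gene:
        raise ExpressionError(
            f"gene mismatch: {treated.gene!r} vs {control.gene!r}"
        )
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def qpcr_fold_changes(df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fold changes from a Ct table.

    Expects columns gene, condition ('control'/'treated'), ct_target,
    ct_reference; biological replicates are averaged (arithmetic mean of
    cycles) per gene and condition before the Livak computation.
    """
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ExpressionError(f"missing column(s): {sorted(missing)}")
    means = df.groupby(["gene", "condition"])[["ct_target", "ct_reference"]].mean()
    rows = []
    for gene in sorted(df["gene"].unique()):
        try:
            t = means.loc[(gene, "treated")]
            c = means.loc[(gene, "control")]
        except KeyError as exc:
            raise ExpressionError(f"gene {gene!r} lacks a {exc.args[0][1]} condition") from exc
        fold = relative_expression(
            CtRecord(gene, "treated", t["ct_target"], t["ct_reference"]),
            CtRecord(gene, "control", c["ct_target"], c["ct_reference"]),
        )
        rows.append({"gene": gene, "fold_change": fold})
    return pd.DataFrame(rows, columns=["gene", "fold_change"])


def log2_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(TPM + pseudocount)."""
    if pseudocount <= 0:
        raise ExpressionError("pseudocount must be positive")
    values = m.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ExpressionError("TPM values must be nonnegative")
    return pd.DataFrame(np.log2(values + pseudocount), index=m.index, columns=m.columns)


def stress_response_filter(
    m: pd.DataFrame,
    detect_threshold: float = DEFAULT_DETECT_THRESHOLD,
    stresses: Sequence[str] = STRESSES,
) -> pd.Series:
    """Class each gene as ``multi_stress`` (detected under at least two of the
    stresses) or ``non_responsive`` (detected under at most one)."""
    missing = [s for s in stresses if s not in m.columns]
    if missing:
        raise ExpressionError(f"missing stress column(s): {missing}")
    values = m[list(stresses)].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ExpressionError("TPM values must be nonnegative")
    detected = (values >= detect_threshold).sum(axis=1)
    return pd.Series(
        np.where(detected >= 2, "multi_stress", "non_responsive"),
        index=m.index,
        name="stress_class",
    )
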