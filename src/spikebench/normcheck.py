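"""Diluted-sample validation of cross-run normalization.

When one condition is loaded at a different on-column amount (the
canonical check uses 1 ug of Sample A vs 0.7 ug of Sample B), correctly
normalized intensities of a background species that is mixed equally in
both samples should still show a median log2 ratio near zero; data left
unnormalized instead shows a shift near log2 of the load ratio.  This
module only detects the failure; it does not fix normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import log2_transform
from .io import QuantMatrix, RunDesign

__all__ = ["NormCheckResult", "normalization_shift", "median_center"]

MIN_UNCHANGED_ENTRIES = 50


@dataclass(frozen=True)
class NormCheckResult:
    """Outcome of the dilution normalization check.

    ``observed_shift`` — median over unchanged-species entries of
    (mean log2 in load group 1 - mean log2 in load group 2).
    ``expected_shift_if_unnormalized`` — log2 of the load ratio.
    ``flag`` is "pass" iff |observed_shift| <= tolerance.
    """

    observed_shift: float
    expected_shift_if_unnormalized: float
    tolerance: float
    n_entries: int
    low_confidence: bool

    @property
    def flag(self) -> str:
        return "pass" if abs(self.observed_shift) <= self.tolerance else "fail"


def normalization_shift(
    matrix: QuantMatrix,
    run_design: RunDesign,
    unchanged_species: str = "human",
    load_ratio: float = 1.0 / 0.7,
    tolerance: float = 0.2,
) -> NormCheckResult:
    """Measure the residual between-load-group shift on a background species.

    Group 1 is condition A (higher load), group 2 condition B.  Entries
    need at least one value per group.  Fewer than 50 usable
    unchanged-species entries marks the result low-confidence.
    """
    if load_ratio <= 0:
        raise ValueError("load_ratio must be positive")
    keep = (matrix.species == unchanged_species).to_numpy()
    sub = matrix.subset(keep)
    log_mat = log2_transform(sub)
    a = log_mat[list(run_design.runs("A"))].mean(axis=1)
    b = log_mat[list(run_design.runs("B"))].mean(axis=1)
    ratios = (a - b).dropna()
    low_confidence = len(ratios) < MIN_UNCHANGED_ENTRIES
    observed = float(ratios.median()) if len(ratios) else math.nan
    return NormCheckResult(
        observed_shift=observed,
        expected_shift_if_unnormalized=math.log2(load_ratio),
        tolerance=tolerance,
        n_entries=int(len(ratios)),
        low_confidence=low_confidence,
    )


def median_center(matrix: QuantMatrix) -> QuantMatrix:
    """Global median-centering of log intensities per run.

    Divides each run's intensities by that run's median so all run
    medians coincide — the minimal normalization that restores a passing
    dilution check after a global shift.
    """
    inten = matrix.intensities
    medians = inten.median(axis=0)
    centered = inten / medians * float(np.exp(np.log(medians).mean()))
    return QuantMatrix(
        centered,
        level=matrix.level,
        species=matrix.species,
        is_contaminant=matrix.is_contaminant,
    )
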