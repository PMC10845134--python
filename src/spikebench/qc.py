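"""Identification/quantification filters and CV statistics.

An entry is *identified* when its data completeness exceeds 50% in both
conditions (with triplicates: a value in at least 2 of 3 replicates in
both Samples A and B).  An identified entry is *quantified* when its
coefficient of variation is below 20% in both conditions.  CVs are
computed on raw (non-log) intensities with the n-1 standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import QuantMatrix, RunDesign

__all__ = [
    "entry_qc",
    "completeness_filter",
    "cv_per_condition",
    "quantified_filter",
    "cv_summary",
    "DEFAULT_CV_THRESHOLD",
    "DEFAULT_MIN_COMPLETENESS",
]

DEFAULT_MIN_COMPLETENESS = 0.5
DEFAULT_CV_THRESHOLD = 20.0


def _condition_values(matrix: QuantMatrix, run_design: RunDesign, cond: str) -> pd.DataFrame:
    return matrix.intensities[list(run_design.runs(cond))]


def completeness_filter(
    matrix: QuantMatrix,
    run_design: RunDesign,
    min_fraction: float = DEFAULT_MIN_COMPLETENESS,
) -> pd.Series:
    """Identified flags: completeness strictly > ``min_fraction`` in A and B."""
    flags = None
    for cond in ("A", "B"):
        vals = _condition_values(matrix, run_design, cond)
        completeness = vals.notna().sum(axis=1) / vals.shape[1]
        ok = completeness > min_fraction
        flags = ok if flags is None else (flags & ok)
    return flags.rename("identified")


def cv_per_condition(matrix: QuantMatrix, run_design: RunDesign) -> pd.DataFrame:
    """Per-entry CV (%) in each condition; NaN where <2 values are present.

    CV = 100 * sd(n-1) / mean on raw intensities.
    """
    out = {}
    for cond in ("A", "B"):
        vals = _condition_values(matrix, run_design, cond)
        n = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[n < 2] = np.nan
        out[f"cv_{cond.lower()}"] = cv
    return pd.DataFrame(out)


def quantified_filter(
    identified: pd.Series,
    cvs: pd.DataFrame,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.Series:
    """Quantified flags: identified AND cv_a < threshold AND cv_b < threshold."""
    ok = identified & (cvs["cv_a"] < cv_threshold) & (cvs["cv_b"] < cv_threshold)
    return ok.fillna(False).rename("quantified")


def entry_qc(
    matrix: QuantMatrix,
    run_design: RunDesign,
    *,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Full per-entry QC table.

    Columns: species, completeness_a/b, cv_a/b, identified, quantified.
    """
    rows = {}
    for cond in ("A", "B"):
        vals = _condition_values(matrix, run_design, cond)
        rows[f"completeness_{cond.lower()}"] = vals.notna().sum(axis=1) / vals.shape[1]
    qc = pd.DataFrame(rows)
    qc = pd.concat([qc, cv_per_condition(matrix, run_design)], axis=1)
    qc.insert(0, "species", matrix.species)
    qc["identified"] = completeness_filter(matrix, run_design, min_completeness)
    qc["quantified"] = quantified_filter(qc["identified"], qc[["cv_a", "cv_b"]], cv_threshold)
    return qc


def cv_summary(qc: pd.DataFrame, scope: str = "quantified") -> dict[str, float]:
    """Mean/median CV (%) over entries in scope, pooled and per condition.

    ``scope`` is "identified" or "quantified".  Pooled statistics combine
    the per-entry CVs of both conditions into one vector; per-condition
    means/medians are reported alongside since the pooling convention is
    a choice.
    """
    if scope not in {"identified", "quantified"}:
        raise ValueError("scope must be 'identified' or 'quantified'")
    sub = qc[qc[scope]]
    if sub.empty:
        raise ValueError(f"no entries in scope {scope!r}")
    pooled = pd.concat([sub["cv_a"], sub["cv_b"]]).dropna()
    return {
        "scope": scope,
        "n_entries": int(len(sub)),
        "mean_cv": float(pooled.mean()),
        "median_cv": float(pooled.median()),
        "mean_cv_a": float(sub["cv_a"].mean()),
        "mean_cv_b": float(sub["cv_b"].mean()),
        "median_cv_a": float(sub["cv_a"].median()),
        "median_cv_b": float(sub["cv_b"].median()),
    }
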