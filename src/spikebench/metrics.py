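"""Ground-truth benchmark metrics: confusion matrix, deFDR, asymmetry
factors, Accuracy/Dispersion/Trueness, and the accuracy verdict.

The differential-expression FDR (deFDR) is FP/(FP+TP) over the
ground-truth confusion matrix — distinct from identification FDR.  The
asymmetry factor of a species' log2-fold-change density is the ratio of
the right to the left half-width at 10% of the maximum density height;
after orienting negative-expectation species, AF < 1 uniformly signals
fold-change underestimation (ratio compression) and AF > 1
overestimation (expansion), with 0.5 and 2 as the undesirable-degree
thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import AMBIGUOUS, UNKNOWN

__all__ = [
    "ConfusionSummary",
    "SpeciesStats",
    "BenchmarkReport",
    "expected_class",
    "confusion_summary",
    "asymmetry_factor",
    "accuracy_statistic",
    "dispersion_statistic",
    "trueness_statistic",
    "species_stats",
    "verdict",
    "DEFAULT_THRESHOLDS",
    "MIN_AF_VALUES",
]

MIN_AF_VALUES = 30

# Accuracy criteria a workflow must meet to be termed accurate.  The two
# thresholds the benchmark procedure itself defines are the 1% deFDR and
# the [0.5, 2] asymmetry-factor band; an additional precision criterion
# on the mean CV of quantified entries (5% is the conventional bar for a
# well-behaved workflow) can be enabled by setting "mean_cv_max".
DEFAULT_THRESHOLDS = {
    "defdr_max": 0.01,
    "mean_cv_max": None,
    "af_min": 0.5,
    "af_max": 2.0,
}


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion-matrix counts and derived rates.

    ``defdr`` = FP/(FP+TP).  ``sensitivity`` = TP/(TP+FN) (the standard
    true-positive rate); ``sensitivity_paper_literal`` = TP/(FP+TP) is
    also carried because the formula is sometimes printed that way.
    Rates are NaN where their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tp_up: int
    tp_down: int

    @property
    def n_tested(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def defdr(self) -> float:
        return self.fp / (self.fp + self.tp) if (self.fp + self.tp) else math.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def sensitivity_paper_literal(self) -> float:
        return self.tp / (self.fp + self.tp) if (self.fp + self.tp) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "tp_up": self.tp_up,
            "tp_down": self.tp_down,
            "defdr": self.defdr,
            "sensitivity": self.sensitivity,
            "sensitivity_paper_literal": self.sensitivity_paper_literal,
            "specificity": self.specificity,
        }


@dataclass
class SpeciesStats:
    species: str
    n: int
    expected_log2fc: float
    median_log2fc: float
    asymmetry_factor: float  # NaN when undefined
    accuracy_contrib: float
    dispersion_contrib: float


@dataclass
class BenchmarkReport:
    """Everything the benchmark computes for one data set."""

    id_counts: dict
    cv_summaries: dict
    confusion: ConfusionSummary
    species: list[SpeciesStats]
    accuracy_stat: float
    dispersion_stat: float
    trueness_stat: float  # NaN when a design species has no quantified entry
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    verdict: str = ""
    violated_criteria: list[str] = field(default_factory=list)


def expected_class(expected_log2fc: float) -> str:
    """Up / Down / Unchanged from a species' expected log2 fold change."""
    if expected_log2fc > 0:
        return "Up"
    if expected_log2fc < 0:
        return "Down"
    return "Unchanged"


def confusion_summary(
    class_labels: pd.Series, expected_classes: pd.Series
) -> ConfusionSummary:
    """Tally the confusion matrix over aligned measured/expected labels.

    TP: measured equals expected and expected is not Unchanged (a
    fold-change magnitude overshoot in the right direction still counts
    as TP).  FP: measured Up/Down but not matching expected — this
    includes calls on Unchanged species and wrong-direction calls, so
    the four counts partition the tested entries exactly.  TN: both
    Unchanged.  FN: expected Up/Down, measured Unchanged.
    """
    m = class_labels.to_numpy()
    e = expected_classes.reindex(class_labels.index).to_numpy()
    changed_m = np.isin(m, ("Up", "Down"))
    changed_e = np.isin(e, ("Up", "Down"))
    tp_mask = changed_e & (m == e)
    fp_mask = changed_m & (m != e)
    tn_mask = (~changed_m) & (~changed_e)
    fn_mask = changed_e & (~changed_m)
    return ConfusionSummary(
        tp=int(tp_mask.sum()),
        fp=int(fp_mask.sum()),
        tn=int(tn_mask.sum()),
        fn=int(fn_mask.sum()),
        tp_up=int((tp_mask & (m == "Up")).sum()),
        tp_down=int((tp_mask & (m == "Down")).sum()),
    )


def asymmetry_factor(
    log2fcs: np.ndarray | pd.Series,
    *,
    orient_negative: bool = False,
    expected_log2fc: float = 0.0,
    grid_size: int = 512,
    height_fraction: float = 0.10,
) -> float:
    """Peak asymmetry factor of the log2-fold-change density.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a ``grid_size``
    grid spanning the data range plus three bandwidths on each side.
    The center line is the grid x of maximum density; the left and right
    x-values are the outermost crossings of ``height_fraction`` times
    the maximum height, located by linear interpolation.  AF =
    (right - center) / (center - left).

    With ``orient_negative`` set and a negative ``expected_log2fc`` the
    values are negated before estimation, so AF < 1 always reads as
    fold-change underestimation regardless of direction.

    Returns NaN (with a warning) for fewer than 30 values or a
    degenerate (zero-width) sample.
    """
    x = np.asarray(log2fcs, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_AF_VALUES:
        warnings.warn(f"asymmetry factor undefined: {len(x)} < {MIN_AF_VALUES} values")
        return math.nan
    if np.ptp(x) == 0:
        warnings.warn("asymmetry factor undefined: zero-width distribution")
        return math.nan
    if orient_negative and expected_log2fc < 0:
        x = -x

    kde = gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    dens = kde(grid)
    i_max = int(np.argmax(dens))
    center = grid[i_max]
    level = height_fraction * dens[i_max]

    def crossing(lo: int, hi: int) -> float:
        # linear interpolation between grid points straddling the level
        x0, x1 = grid[lo], grid[hi]
        y0, y1 = dens[lo], dens[hi]
        if y1 == y0:
            return x0
        return x0 + (level - y0) * (x1 - x0) / (y1 - y0)

    above = dens >= level
    j_left = int(np.argmax(above))  # first grid point at/above the level
    x_left = crossing(j_left - 1, j_left) if j_left > 0 else grid[0]
    j_right = len(dens) - 1 - int(np.argmax(above[::-1]))  # last point at/above
    x_right = crossing(j_right + 1, j_right) if j_right < len(dens) - 1 else grid[-1]

    left_dist = center - x_left
    right_dist = x_right - center
    if left_dist <= 0:
        warnings.warn("asymmetry factor undefined: degenerate left half-width")
        return math.nan
    return float(right_dist / left_dist)


def _with_truth(results: pd.DataFrame, expected: dict[str, float]) -> pd.DataFrame:
    sub = results[results["species"].isin(expected)]
    return sub


def accuracy_statistic(
    results: pd.DataFrame, expected: dict[str, float]
) -> tuple[float, dict[str, float]]:
    """Mean |measured - expected| log2 fold change, overall and per species.

    Overall is pooled over entries (equivalently the entry-count-weighted
    mean of the per-species values).
    """
    sub = _with_truth(results, expected)
    if sub.empty:
        raise ValueError("no quantified entries with ground truth")
    dev = (sub["log2fc"] - sub["species"].map(expected)).abs()
    per_species = dev.groupby(sub["species"]).mean().to_dict()
    return float(dev.mean()), per_species


def dispersion_statistic(results: pd.DataFrame) -> tuple[float, dict[str, float]]:
    """Mean |measured - species median| log2 fold change (spread measure)."""
    sub = results[~results["species"].isin([AMBIGUOUS, UNKNOWN])]
    if sub.empty:
        raise ValueError("no quantified entries with a species label")
    medians = sub.groupby("species")["log2fc"].transform("median")
    dev = (sub["log2fc"] - medians).abs()
    per_species = dev.groupby(sub["species"]).mean().to_dict()
    return float(dev.mean()), per_species


def trueness_statistic(
    results: pd.DataFrame, expected: dict[str, float]
) -> tuple[float, dict[str, float]]:
    """Sum over design species of |median measured - expected| log2FC.

    If a design species has no quantified entry its contribution is NaN
    and the total is NaN ("not evaluable"), with a warning.
    """
    sub = _with_truth(results, expected)
    medians = sub.groupby("species")["log2fc"].median()
    contribs: dict[str, float] = {}
    total = 0.0
    evaluable = True
    for sp, exp_fc in expected.items():
        if sp in medians.index:
            contribs[sp] = float(abs(medians[sp] - exp_fc))
            total += contribs[sp]
        else:
            warnings.warn(f"design species {sp!r} absent from quantified set; trueness not evaluable")
            contribs[sp] = math.nan
            evaluable = False
    return (total if evaluable else math.nan), contribs


def species_stats(
    results: pd.DataFrame,
    expected: dict[str, float],
    *,
    orient_negative: bool = True,
) -> list[SpeciesStats]:
    """Per-species summary: median log2FC, oriented AF, stat contributions."""
    _, acc = accuracy_statistic(results, expected)
    _, disp = dispersion_statistic(results)
    out = []
    for sp, exp_fc in expected.items():
        vals = results.loc[results["species"] == sp, "log2fc"]
        af = (
            asymmetry_factor(vals, orient_negative=orient_negative, expected_log2fc=exp_fc)
            if len(vals)
            else math.nan
        )
        out.append(
            SpeciesStats(
                species=sp,
                n=int(len(vals)),
                expected_log2fc=exp_fc,
                median_log2fc=float(vals.median()) if len(vals) else math.nan,
                asymmetry_factor=af,
                accuracy_contrib=acc.get(sp, math.nan),
                dispersion_contrib=disp.get(sp, math.nan),
            )
        )
    return out


def verdict(
    confusion: ConfusionSummary,
    mean_cv_quantified: float,
    species: list[SpeciesStats],
    thresholds: dict | None = None,
) -> tuple[str, list[str]]:
    """Accuracy verdict from the threshold criteria.

    A workflow is accurate only if deFDR <= 1% and every defined
    per-species asymmetry factor lies within [0.5, 2]; when a
    "mean_cv_max" threshold is configured, the mean CV of quantified
    entries must also stay below it.  A criterion whose statistic is
    undefined (NaN) makes the verdict "inaccurate (not evaluable)".
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    violated: list[str] = []
    not_evaluable: list[str] = []

    if math.isnan(confusion.defdr):
        not_evaluable.append("deFDR")
    elif confusion.defdr > thr["defdr_max"]:
        violated.append("deFDR")

    if thr.get("mean_cv_max") is not None:
        if math.isnan(mean_cv_quantified):
            not_evaluable.append("mean_cv")
        elif mean_cv_quantified > thr["mean_cv_max"]:
            violated.append("mean_cv")

    for sp in species:
        if math.isnan(sp.asymmetry_factor):
            continue  # undefined AFs are warned about upstream, not fatal
        if not thr["af_min"] <= sp.asymmetry_factor <= thr["af_max"]:
            violated.append(f"asymmetry:{sp.species}")

    if not_evaluable:
        return "inaccurate (not evaluable)", violated + [f"not evaluable: {c}" for c in not_evaluable]
    return ("accurate" if not violated else "inaccurate"), violated
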