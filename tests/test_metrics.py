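import math

import numpy as np
import pandas as pd
import pytest

from spikebench import (
    ConfusionSummary,
    SpeciesStats,
    accuracy_statistic,
    asymmetry_factor,
    confusion_summary,
    dispersion_statistic,
    expected_class,
    trueness_statistic,
    verdict,
)


def _labels(pairs):
    """pairs: list of (measured, expected) -> aligned Series."""
    idx = [f"e{i}" for i in range(len(pairs))]
    measured = pd.Series([m for m, _ in pairs], index=idx)
    expected = pd.Series([e for _, e in pairs], index=idx)
    return measured, expected


class TestExpectedClass:
    @pytest.mark.parametrize("fc,cls", [(1.0, "Up"), (-2.0, "Down"), (0.0, "Unchanged")])
    def test_sign_rule(self, fc, cls):
        assert expected_class(fc) == cls


class TestConfusion:
    def test_defdr_hand_example(self):
        pairs = [("Up", "Up")] * 99 + [("Up", "Unchanged")]
        cs = confusion_summary(*_labels(pairs))
        assert cs.tp == 99 and cs.fp == 1
        assert cs.defdr == pytest.approx(0.01)

    def test_wrong_direction_is_fp_not_fn(self):
        cs = confusion_summary(*_labels([("Down", "Up")]))
        assert cs.fp == 1 and cs.fn == 0 and cs.tp == 0

    def test_all_unchanged_degenerate(self):
        cs = confusion_summary(*_labels([("Unchanged", "Unchanged")] * 5))
        assert cs.tn == 5 and cs.tp == 0 and cs.fp == 0
        assert math.isnan(cs.defdr)

    def test_counts_partition_tested_entries(self):
        rng = np.random.default_rng(0)
        classes = ["Up", "Down", "Unchanged"]
        pairs = [(rng.choice(classes), rng.choice(classes)) for _ in range(500)]
        cs = confusion_summary(*_labels(pairs))
        assert cs.tp + cs.fp + cs.tn + cs.fn == 500

    def test_defdr_invariant_under_duplication(self):
        rng = np.random.default_rng(1)
        classes = ["Up", "Down", "Unchanged"]
        pairs = [(rng.choice(classes), rng.choice(classes)) for _ in range(100)]
        cs1 = confusion_summary(*_labels(pairs))
        cs2 = confusion_summary(*_labels(pairs * 3))
        assert cs2.defdr == pytest.approx(cs1.defdr)

    def test_sensitivity_conventions(self):
        # 3 TP, 1 FP, 2 FN, 4 TN
        pairs = ([("Up", "Up")] * 3 + [("Up", "Unchanged")]
                 + [("Unchanged", "Up")] * 2 + [("Unchanged", "Unchanged")] * 4)
        cs = confusion_summary(*_labels(pairs))
        assert cs.sensitivity == pytest.approx(3 / 5)          # TP/(TP+FN)
        assert cs.sensitivity_paper_literal == pytest.approx(3 / 4)  # TP/(FP+TP)
        assert cs.specificity == pytest.approx(4 / 5)          # TN/(TN+FP)


def _histogram_af_oracle(values: np.ndarray, bins: int = 400) -> float:
    """Direct 10%-height measurement on an oversampled histogram."""
    hist, edges = np.histogram(values, bins=bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    i_max = int(np.argmax(hist))
    level = 0.1 * hist[i_max]
    above = hist >= level
    j_left = int(np.argmax(above))
    j_right = len(hist) - 1 - int(np.argmax(above[::-1]))

    def interp(i0, i1):
        if hist[i1] == hist[i0]:
            return centers[i0]
        return centers[i0] + (level - hist[i0]) * (centers[i1] - centers[i0]) / (
            hist[i1] - hist[i0]
        )

    x_left = interp(j_left - 1, j_left) if j_left > 0 else centers[0]
    x_right = interp(j_right + 1, j_right) if j_right < len(hist) - 1 else centers[-1]
    center = centers[i_max]
    return (x_right - center) / (center - x_left)


class TestAsymmetryFactor:
    def test_symmetric_gaussian_near_one(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(1.0, 0.1, 10_000)
        assert asymmetry_factor(vals) == pytest.approx(1.0, abs=0.1)

    def test_right_skew_exceeds_one_and_matches_histogram_oracle(self):
        rng = np.random.default_rng(42)
        big = rng.gamma(3.0, 1.0, 400_000) + 0.3
        oracle = _histogram_af_oracle(big)
        af = asymmetry_factor(big)
        assert af > 1.0
        assert af == pytest.approx(oracle, rel=0.10)

    def test_mirror_symmetry_with_orientation(self):
        rng = np.random.default_rng(3)
        skewed = rng.gamma(3.0, 0.2, 5_000) + 0.3
        af_pos = asymmetry_factor(skewed, orient_negative=True, expected_log2fc=1.0)
        af_neg = asymmetry_factor(-skewed, orient_negative=True, expected_log2fc=-1.0)
        assert af_neg == pytest.approx(af_pos, rel=1e-6)

    def test_too_few_values_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(asymmetry_factor(np.ones(10) + np.arange(10) * 0.01))

    def test_zero_width_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(asymmetry_factor(np.full(100, 2.0)))


EXPECTED = {"human": 0.0, "yeast": 1.0, "ecoli": -2.0}


def _results(species_values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for sp, vals in species_values.items():
        rows.extend({"species": sp, "log2fc": v} for v in vals)
    return pd.DataFrame(rows, index=[f"e{i}" for i in range(len(rows))])


class TestSummaryStatistics:
    def test_accuracy_zero_at_expectation(self):
        res = _results({"human": [0.0, 0.0], "yeast": [1.0], "ecoli": [-2.0]})
        overall, _ = accuracy_statistic(res, EXPECTED)
        assert overall == 0.0

    def test_accuracy_hand_example(self):
        res = _results({"yeast": [1.5, 0.5]})
        overall, per = accuracy_statistic(res, {"yeast": 1.0})
        assert overall == pytest.approx(0.5)
        assert per["yeast"] == pytest.approx(0.5)

    def test_accuracy_overall_is_entry_weighted(self):
        res = _results({"human": [0.2, -0.2, 0.2, -0.2], "yeast": [2.0]})
        overall, per = accuracy_statistic(res, {"human": 0.0, "yeast": 1.0})
        assert overall == pytest.approx((4 * 0.2 + 1 * 1.0) / 5)
        assert per["human"] == pytest.approx(0.2) and per["yeast"] == pytest.approx(1.0)

    def test_dispersion_hand_example(self):
        res = _results({"human": [0.0, 1.0, 2.0]})
        overall, _ = dispersion_statistic(res)
        assert overall == pytest.approx(2 / 3)

    def test_dispersion_translation_invariant(self):
        base = _results({"human": [0.0, 1.0, 2.0]})
        shifted = _results({"human": [5.0, 6.0, 7.0]})
        assert dispersion_statistic(base)[0] == pytest.approx(dispersion_statistic(shifted)[0])

    def test_trueness_hand_example(self):
        res = _results({"human": [0.0], "yeast": [0.8], "ecoli": [-1.7]})
        total, contribs = trueness_statistic(res, EXPECTED)
        assert total == pytest.approx(0.5)
        assert contribs["yeast"] == pytest.approx(0.2)

    def test_trueness_missing_species_not_evaluable(self):
        res = _results({"human": [0.0], "yeast": [1.0]})
        with pytest.warns(UserWarning, match="not evaluable"):
            total, contribs = trueness_statistic(res, EXPECTED)
        assert math.isnan(total) and math.isnan(contribs["ecoli"])


def _species_stats(afs: dict[str, float]) -> list[SpeciesStats]:
    return [
        SpeciesStats(sp, 100, EXPECTED[sp], EXPECTED[sp], af, 0.1, 0.1)
        for sp, af in afs.items()
    ]


class TestVerdict:
    def test_all_within_is_accurate(self):
        cs = ConfusionSummary(tp=995, fp=5, tn=1000, fn=10, tp_up=700, tp_down=295)
        v, violated = verdict(cs, 4.0, _species_stats({"human": 0.9, "yeast": 1.1, "ecoli": 1.0}))
        assert v == "accurate" and violated == []

    def test_defdr_violation(self):
        cs = ConfusionSummary(tp=94, fp=6, tn=100, fn=0, tp_up=94, tp_down=0)
        v, violated = verdict(cs, 4.0, _species_stats({"human": 1.0}))
        assert v == "inaccurate" and "deFDR" in violated

    def test_asymmetry_violation(self):
        cs = ConfusionSummary(tp=100, fp=0, tn=100, fn=0, tp_up=100, tp_down=0)
        v, violated = verdict(cs, 4.0, _species_stats({"yeast": 0.4}))
        assert v == "inaccurate" and "asymmetry:yeast" in violated

    def test_mean_cv_criterion_when_configured(self):
        cs = ConfusionSummary(tp=100, fp=0, tn=100, fn=0, tp_up=100, tp_down=0)
        stats = _species_stats({"human": 1.0})
        v, violated = verdict(cs, 8.0, stats, {"mean_cv_max": 5.0})
        assert v == "inaccurate" and "mean_cv" in violated
        v2, _ = verdict(cs, 4.0, stats, {"mean_cv_max": 5.0})
        assert v2 == "accurate"

    def test_undefined_defdr_not_evaluable(self):
        cs = ConfusionSummary(tp=0, fp=0, tn=100, fn=0, tp_up=0, tp_down=0)
        v, violated = verdict(cs, 4.0, _species_stats({"human": 1.0}))
        assert v == "inaccurate (not evaluable)"
        assert any("deFDR" in c for c in violated)
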