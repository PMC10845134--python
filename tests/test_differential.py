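import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spikebench import (
    EBayesPrior,
    QuantMatrix,
    RunDesign,
    bh_adjust,
    classify_entries,
    estimate_ebayes_prior,
    fit_group_means,
    log2_transform,
    moderated_test,
)


def _fits_from_arrays(A: np.ndarray, B: np.ndarray) -> pd.DataFrame:
    na, nb = A.shape[1], B.shape[1]
    ss = A.var(1, ddof=1) * (na - 1) + B.var(1, ddof=1) * (nb - 1)
    df = na + nb - 2
    return pd.DataFrame(
        {
            "mean_a": A.mean(1),
            "mean_b": B.mean(1),
            "log2fc": A.mean(1) - B.mean(1),
            "n_a": na,
            "n_b": nb,
            "s_sq": ss / df,
            "df": df,
        }
    )


class _OrdinaryPrior:
    """d0 = 0 limit (no shrinkage); bypasses the EBayesPrior d0>0 invariant."""

    d0 = 0.0
    s0_sq = 1.0


class TestLog2Transform:
    def test_values_and_missing(self, run_design_3v3):
        inten = pd.DataFrame([[8, 1, np.nan, 2, 4, 16]], index=["e"],
                             columns=list(run_design_3v3.run_ids))
        out = log2_transform(QuantMatrix(inten))
        assert out.iloc[0, 0] == 3.0 and out.iloc[0, 1] == 0.0
        assert np.isnan(out.iloc[0, 2])

    def test_zero_present_rejected(self, run_design_3v3):
        inten = pd.DataFrame([[0.0, 1, 1, 1, 1, 1]], index=["e"],
                             columns=list(run_design_3v3.run_ids))
        m = QuantMatrix(inten)
        m.intensities.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(m)


class TestFitGroupMeans:
    def test_constant_groups(self, run_design_3v3):
        log_mat = pd.DataFrame([[3, 3, 3, 2, 2, 2]], index=["e"],
                               columns=list(run_design_3v3.run_ids))
        fits = fit_group_means(log_mat, run_design_3v3)
        row = fits.iloc[0]
        assert row["log2fc"] == 1.0 and row["s_sq"] == 0.0 and row["df"] == 4

    def test_hand_pooled_variance(self):
        rd = RunDesign(("A1", "A2", "B1", "B2"), ("A", "A", "B", "B"), (1, 2, 1, 2))
        log_mat = pd.DataFrame([[1, 3, 2, 2]], index=["e"], columns=list(rd.run_ids))
        row = fit_group_means(log_mat, rd).iloc[0]
        assert row["log2fc"] == 0.0 and row["s_sq"] == 1.0 and row["df"] == 2

    def test_insufficient_values_excluded(self, run_design_3v3):
        log_mat = pd.DataFrame([[5, np.nan, np.nan, 2, 2, 2]], index=["e"],
                               columns=list(run_design_3v3.run_ids))
        with pytest.warns(UserWarning, match="excluded"):
            fits = fit_group_means(log_mat, run_design_3v3)
        assert len(fits) == 0


class TestEBayesPrior:
    def test_recovery_from_hierarchical_model(self):
        d0, s0_sq, n, df = 4.0, 0.05, 5000, 4
        rng = np.random.default_rng(42)
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s_sq = sigma2 * rng.chisquare(df, n) / df
        prior = estimate_ebayes_prior(s_sq, np.full(n, df))
        assert prior.d0 == pytest.approx(d0, rel=0.30)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_ebayes_prior(np.full(100, 0.25), np.full(100, 4))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25, rel=1e-6)

    def test_too_few_entries_raises(self):
        with pytest.raises(ValueError, match="too few"):
            estimate_ebayes_prior(np.array([0.1] * 5), np.array([4] * 5))

    def test_matches_limma_fitFDist(self, tmp_path):
        """Cross-check hyperparameters, t and p against Bioconductor limma."""
        rng = np.random.default_rng(5)
        A = rng.normal(12, 0.3, (60, 3))
        B = rng.normal(12, 0.3, (60, 3))
        B[:10] += 1.0
        mat = pd.DataFrame(
            np.hstack([A, B]), columns=["A1", "A2", "A3", "B1", "B2", "B3"],
            index=[f"e{i}" for i in range(60)],
        )
        tsv = tmp_path / "m.tsv"
        mat.to_csv(tsv, sep="\t")
        rscript = tmp_path / "ref.R"
        rscript.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- read.delim("{tsv}", row.names=1)\n'
            'design <- cbind(Intercept=1, AvsB=c(1,1,1,0,0,0))\n'
            'fit <- eBayes(lmFit(as.matrix(x), design))\n'
            'out <- data.frame(t=fit$t[,"AvsB"], p=fit$p.value[,"AvsB"],'
            ' d0=fit$df.prior, s0=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path / "ref.tsv"}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)

        fits = _fits_from_arrays(A, B)
        prior = estimate_ebayes_prior(fits["s_sq"].to_numpy(), fits["df"].to_numpy())
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        res = moderated_test(fits, prior)
        assert np.abs(res["t_mod"].to_numpy() - ref["t"].to_numpy()).max() < 1e-9
        assert np.abs(res["p_raw"].to_numpy() - ref["p"].to_numpy()).max() < 1e-9


class TestModeratedTest:
    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        A = rng.normal(10, 1, (200, 3))
        B = rng.normal(10, 1, (200, 3))
        res = moderated_test(_fits_from_arrays(A, B), _OrdinaryPrior())
        t_ref, p_ref = stats.ttest_ind(A.T, B.T)
        assert np.abs(res["t_mod"].to_numpy() - t_ref).max() < 1e-12
        assert np.abs(res["p_raw"].to_numpy() - p_ref).max() < 1e-12

    def test_zero_fold_change_gives_p_one(self):
        fits = pd.DataFrame(
            {"mean_a": [1.0], "mean_b": [1.0], "log2fc": [0.0],
             "n_a": [3], "n_b": [3], "s_sq": [0.5], "df": [4]}
        )
        res = moderated_test(fits, EBayesPrior(d0=4, s0_sq=0.5))
        assert res["t_mod"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_infinite_d0_closed_form(self):
        fits = pd.DataFrame(
            {"mean_a": [2.0], "mean_b": [0.0], "log2fc": [2.0],
             "n_a": [3], "n_b": [3], "s_sq": [123.0], "df": [4]}
        )
        res = moderated_test(fits, EBayesPrior(d0=math.inf, s0_sq=1.0))
        t_expected = 2.0 / math.sqrt(2.0 / 3.0)
        assert res["t_mod"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert res["p_raw"].iloc[0] == pytest.approx(2 * stats.norm.sf(t_expected), rel=1e-12)


def _bh_brute_force(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    for rank, idx in enumerate(order):
        adj[idx] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank, n)), 1.0
        )
    return adj


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.all(bh_adjust(np.ones(5)) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, p_list):
        p = np.array(p_list)
        assert np.allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "p_adj,log2fc,expected",
        [
            (0.005, 1.2, "Up"),
            (0.005, 0.4, "Unchanged"),
            (0.02, -3.0, "Unchanged"),
            (0.005, -0.6, "Down"),
            (0.005, 25.0, "Up"),  # no upper limit on the fold change
        ],
    )
    def test_rule(self, p_adj, log2fc, expected):
        df = pd.DataFrame({"p_adj": [p_adj], "log2fc": [log2fc]})
        assert classify_entries(df).iloc[0] == expected

    def test_tightening_alpha_is_monotone(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"p_adj": rng.random(300), "log2fc": rng.normal(0, 2, 300)})
        counts = [
            (classify_entries(df, alpha=a) != "Unchanged").sum()
            for a in (0.1, 0.05, 0.01, 0.001)
        ]
        assert counts == sorted(counts, reverse=True)
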