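"""Differential-expression core: normalization, pooled fits, variance
moderation, BH adjustment and DE calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from contrastdep.de import (
    DECallConfig,
    SampleDesign,
    VariancePrior,
    bh_fdr,
    call_de_genes,
    estimate_prior,
    filter_low_counts,
    fit_gene_models,
    moderate,
    normalize_counts,
)
from conftest import toy_counts


def _frame(rows, samples):
    return pd.DataFrame(
        rows,
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
        columns=samples,
    )


class TestNormalize:
    def test_cpm_zero_count_formula(self):
        # library of exactly 1e6: a zero count maps to log2(prior) = -1
        counts = _frame([[0], [1_000_000]], ["s1"])
        norm = normalize_counts(counts, "cpm_log2", prior_count=0.5)
        assert norm.values.loc["g0", "s1"] == pytest.approx(-1.0, abs=1e-12)

    def test_identical_columns_normalize_identically(self):
        col = [3, 10, 0, 55]
        counts = _frame([[c, c] for c in col], ["s1", "s2"])
        for method in ("cpm_log2", "median_of_ratios_log2"):
            norm = normalize_counts(counts, method)
            pd.testing.assert_series_equal(
                norm.values["s1"], norm.values["s2"], check_names=False
            )

    def test_median_of_ratios_depth_invariance(self):
        """Doubling one sample's counts preserves all between-sample contrasts
        up to the prior-count perturbation (plus a constant log2 offset from
        the geometric-mean reference, which cancels in contrasts)."""
        rng = np.random.default_rng(8)
        counts = _frame(rng.poisson(200, size=(50, 4)) + 1, list("abcd"))
        doubled = counts.copy()
        doubled["a"] = 2 * doubled["a"]
        v1 = normalize_counts(counts, "median_of_ratios_log2").values
        v2 = normalize_counts(doubled, "median_of_ratios_log2").values
        contrast1 = v1["a"] - v1["b"]
        contrast2 = v2["a"] - v2["b"]
        assert np.max(np.abs(contrast1 - contrast2)) < 0.01  # prior perturbation only

    def test_monotone_in_counts_within_sample(self):
        counts = _frame([[0], [5], [50], [500]], ["s1"])
        for method in ("cpm_log2", "median_of_ratios_log2"):
            # median-of-ratios needs all-positive reference genes
            c = counts + 1 if method.startswith("median") else counts
            v = normalize_counts(c, method).values["s1"].to_numpy()
            assert np.all(np.diff(v) > 0)

    def test_all_zero_sample_named_in_error(self):
        counts = _frame([[5, 0], [3, 0]], ["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            normalize_counts(counts)

    def test_negative_counts_rejected(self):
        counts = _frame([[1, -2]], ["s1", "s2"])
        with pytest.raises(ValueError):
            normalize_counts(counts)


class TestFit:
    def test_two_group_hand_example(self):
        # KO = [2, 4], control = [1, 3] in log2 units
        values = _frame([[2.0, 4.0, 1.0, 3.0]], ["k1", "k2", "c1", "c2"])
        from contrastdep.de import NormalizedMatrix

        norm = NormalizedMatrix(values, pd.Series(1.0, index=values.columns), 0.5, "cpm_log2")
        design = SampleDesign(
            groups={"k1": "ko", "k2": "ko", "c1": "ctrl", "c2": "ctrl"},
            contrast=("ko", "ctrl"),
        )
        fit = fit_gene_models(norm, design)
        assert fit.loc["g0", "beta"] == pytest.approx(1.0)
        assert fit.loc["g0", "s2"] == pytest.approx(2.0)
        assert fit.loc["g0", "df_residual"] == 2
        assert fit.loc["g0", "stdev_unscaled"] == pytest.approx(1.0)
        se = np.sqrt(fit.loc["g0", "s2"]) * fit.loc["g0", "stdev_unscaled"]
        assert se == pytest.approx(np.sqrt(2.0))

    def test_constant_gene_has_zero_beta_and_variance(self):
        counts, design = toy_counts()
        norm = normalize_counts(counts)
        norm.values.iloc[0] = 3.7  # identical log2 expression in every sample
        fit = fit_gene_models(norm, design)
        assert fit.iloc[0]["beta"] == pytest.approx(0.0, abs=1e-12)
        assert fit.iloc[0]["s2"] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_contrast_negates_beta(self):
        counts, design = toy_counts()
        norm = normalize_counts(counts)
        fit = fit_gene_models(norm, design)
        flipped = SampleDesign(groups=design.groups, contrast=design.contrast[::-1])
        fit2 = fit_gene_models(norm, flipped)
        np.testing.assert_allclose(fit2["beta"], -fit["beta"])
        np.testing.assert_allclose(fit2["s2"], fit["s2"])

    def test_small_group_rejected(self):
        counts, _ = toy_counts()
        design = SampleDesign(
            groups={"s0": "ko", "s1": "ctrl", "s2": "ctrl"}, contrast=("ko", "ctrl")
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_gene_models(normalize_counts(counts), design)

    def test_sample_permutation_invariance(self):
        counts, design = toy_counts()
        shuffled = counts[list(counts.columns[::-1])]
        f1 = fit_gene_models(normalize_counts(counts), design)
        f2 = fit_gene_models(normalize_counts(shuffled), design)
        pd.testing.assert_frame_equal(f1, f2)


class TestPrior:
    def test_identical_variances_cap_d0(self):
        prior = estimate_prior(np.ones(100), 4.0)
        assert prior.d0 >= 1e6
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_two_equal_variances(self):
        prior = estimate_prior([1.0, 1.0], 4.0)
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_parameter_recovery(self):
        # s2_g | sg2 ~ sg2 * chi2_d / d with sg2 ~ s0^2 d0 / chi2_d0
        rng = np.random.default_rng(5)
        d0_true, s0_true, d = 4.0, 1.0, 4
        sg2 = s0_true * d0_true / rng.chisquare(d0_true, 100_000)
        s2 = sg2 * rng.chisquare(d, 100_000) / d
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)

    def test_too_few_positive_variances(self):
        with pytest.raises(ValueError):
            estimate_prior([0.0, 1.0], 4.0)


class TestModerate:
    @staticmethod
    def _fit(beta, s2, df, u):
        return pd.DataFrame(
            {
                "beta": np.atleast_1d(beta),
                "s2": np.atleast_1d(s2),
                "df_residual": float(df),
                "stdev_unscaled": float(u),
            },
            index=pd.Index([f"g{i}" for i in range(np.size(beta))], name="gene_id"),
        )

    def test_posterior_variance_arithmetic(self):
        res = moderate(self._fit(1.0, 2.0, 2, 1.0), VariancePrior(d0=4.0, s0_sq=1.0))
        assert res["s2_post"].iloc[0] == pytest.approx(8.0 / 6.0)
        assert res["df_total"].iloc[0] == pytest.approx(6.0)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        """d0 = 0 reproduces the pooled two-sample t-test (scipy as oracle)."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            n1, n2 = rng.integers(3, 8, 2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            beta = x.mean() - y.mean()
            s2 = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
            s2 /= n1 + n2 - 2
            u = np.sqrt(1 / n1 + 1 / n2)
            res = moderate(
                self._fit(beta, s2, n1 + n2 - 2, u), VariancePrior(d0=0.0, s0_sq=1.0)
            )
            t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
            assert res["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
            assert res["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10)

    def test_zero_beta_gives_p_one(self):
        res = moderate(self._fit(0.0, 1.0, 4, 1.0), VariancePrior(d0=4.0, s0_sq=1.0))
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_sign_of_t_matches_beta(self):
        res = moderate(
            self._fit([-2.0, 3.0], [1.0, 1.0], 4, 1.0), VariancePrior(d0=2.0, s0_sq=1.0)
        )
        assert np.all(np.sign(res["t"]) == np.sign(res["beta"]))

    def test_shrinkage_monotonicity(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 200) / 4
        prior = VariancePrior(d0=4.0, s0_sq=1.0)
        res = moderate(self._fit(np.zeros(200), s2, 4, 1.0), prior)
        assert np.all(
            np.abs(res["s2_post"] - prior.s0_sq) <= np.abs(s2 - prior.s0_sq) + 1e-12
        )

    def test_zero_posterior_variance_sentinel(self):
        res = moderate(self._fit(1.0, 0.0, 4, 1.0), VariancePrior(d0=0.0, s0_sq=1.0))
        assert np.isinf(res["t"].iloc[0]) and res["t"].iloc[0] > 0
        assert res["p"].iloc[0] == 0.0


def _bh_exhaustive(p):
    """Independent oracle: q_i = min_{j: p_j ranked >= rank(i)} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        cands = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(cands))
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_exhaustive_definition(self, p):
        np.testing.assert_allclose(bh_fdr(p), _bh_exhaustive(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)


class TestCalls:
    @staticmethod
    def _results(names, beta, q):
        return pd.DataFrame(
            {"beta": beta, "q": q, "p": q}, index=pd.Index(names, name="gene_id")
        )

    def test_threshold_boundaries(self):
        res = self._results(
            ["at_fc", "under_fc", "at_fdr"],
            [np.log2(1.5), 0.5, 1.0],
            [0.049, 0.001, 0.05],
        )
        calls = call_de_genes(res)["call"]
        assert calls["at_fc"] == "up"  # FC boundary inclusive
        assert calls["under_fc"] == "ns"  # fails FC despite tiny q
        assert calls["at_fdr"] == "ns"  # FDR boundary exclusive

    def test_down_call(self):
        res = self._results(["g"], [-1.0], [0.01])
        assert call_de_genes(res)["call"].iloc[0] == "down"

    def test_knockout_targets_excluded(self):
        res = self._results(["Insr", "Igf1r", "Actb"], [2.0, 2.0, 2.0], [0.001] * 3)
        out = call_de_genes(res, DECallConfig(exclude_genes=("Insr", "Igf1r")))
        assert list(out.index) == ["Actb"]

    def test_low_count_filter(self):
        counts, design = toy_counts()
        counts.iloc[0] = 1  # 6 total counts < 10
        kept = filter_low_counts(counts, design, min_total=10)
        assert counts.index[0] not in kept.index
        assert len(kept) == len(counts) - 1
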