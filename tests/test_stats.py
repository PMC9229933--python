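"""Per-bin model statistics against independent oracles: the classical
pooled-variance t-test, a permutation test, brute-force Benjamini–Hochberg,
and statsmodels OLS."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nmrbin.stats import (
    assign_tier,
    auto_pseudocount,
    bh_adjust,
    fit_bin_model,
    group_ratio,
)
from nmrbin.types import BinMatrix, SampleMetadata, ValidationError


def _two_group_matrix(hsc_values, lsc_values, week=14, bin_label="1.00"):
    """One-bin matrix + metadata for a two-group comparison at one week."""
    vals = list(hsc_values) + list(lsc_values)
    ids = [f"h{i}" for i in range(len(hsc_values))] + [f"l{i}" for i in range(len(lsc_values))]
    meta = [
        SampleMetadata(s, s, f"pen_{s}", "HSC" if s.startswith("h") else "LSC", week)
        for s in ids
    ]
    df = pd.DataFrame({bin_label: vals}, index=ids)
    return BinMatrix(data=df, stage_tag="thresholded"), meta


def bh_brute_force(p):
    """Independent oracle: the literal step-up definition, q_(i) =
    min_{j>=i} m p_(j)/j capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestGroupRatio:
    def test_direct_arithmetic(self):
        m, meta = _two_group_matrix([2.0, 4.0], [4.0, 4.0])
        assert group_ratio(m, meta, 14)["1.00"] == 0.75

    def test_identical_groups_ratio_one(self):
        m, meta = _two_group_matrix([5.0, 5.0], [5.0, 5.0])
        assert group_ratio(m, meta, 14)["1.00"] == 1.0

    def test_nonpositive_lsc_mean_flagged_undefined(self, caplog):
        m, meta = _two_group_matrix([2.0, 4.0], [0.0, 0.0])
        with caplog.at_level("WARNING"):
            r = group_ratio(m, meta, 14)
        assert np.isnan(r["1.00"])
        assert any("undefined" in rec.message for rec in caplog.records)

    def test_missing_group_is_error(self):
        m, meta = _two_group_matrix([2.0], [3.0], week=14)
        with pytest.raises(ValidationError, match="22"):
            group_ratio(m, meta, 22)


class TestFitBinModel:
    def test_matches_closed_form_pooled_t(self):
        """OLS treatment t on the identity scale equals the classical
        pooled-variance two-sample t: t = -6.1237, df = 4, p ~ 0.0036."""
        m, meta = _two_group_matrix([10.0, 12.0, 14.0], [20.0, 22.0, 24.0])
        (res,) = fit_bin_model(m, meta, transform="identity")
        assert res.t_stat == pytest.approx(-6.123724356957945, abs=1e-9)
        assert res.df == 4
        t_sp, p_sp = sps.ttest_ind([10, 12, 14], [20, 22, 24], equal_var=True)
        assert res.t_stat == pytest.approx(t_sp, abs=1e-6)
        assert res.p_raw == pytest.approx(p_sp, abs=1e-6)
        assert res.p_raw == pytest.approx(0.003602, abs=1e-5)

    def test_oracle_equivalence_on_many_random_bins(self):
        """Vectorised per-week OLS == scipy pooled t across 50 random bins."""
        rng = np.random.default_rng(7)
        hsc = rng.lognormal(12, 0.5, size=(6, 50))
        lsc = rng.lognormal(12, 0.5, size=(6, 50))
        ids = [f"h{i}" for i in range(6)] + [f"l{i}" for i in range(6)]
        meta = [
            SampleMetadata(s, s, s, "HSC" if s[0] == "h" else "LSC", 14) for s in ids
        ]
        labels = [f"{0.01 * j:.2f}" for j in range(50)]
        m = BinMatrix(
            data=pd.DataFrame(np.vstack([hsc, lsc]), index=ids, columns=labels),
            stage_tag="thresholded",
        )
        results = fit_bin_model(m, meta, transform="identity")
        t_sp, p_sp = sps.ttest_ind(hsc, lsc, axis=0, equal_var=True)
        np.testing.assert_allclose([r.t_stat for r in results], t_sp, atol=1e-6)
        np.testing.assert_allclose([r.p_raw for r in results], p_sp, atol=1e-6)

    def test_matches_statsmodels_ols_on_log2_scale(self):
        """Cross-check the in-repo normal-equations fit against the
        statsmodels formula interface on the log2 test scale."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        m, meta = _two_group_matrix(rng.lognormal(12, 0.3, 6), rng.lognormal(12, 0.3, 6))
        pc = auto_pseudocount(m)
        (res,) = fit_bin_model(m, meta, transform="log2")
        df = pd.DataFrame(
            {
                "y": np.log2(m.values[:, 0] + pc),
                "treat": ["HSC"] * 6 + ["LSC"] * 6,
            }
        )
        fit = smf.ols("y ~ C(treat, Treatment('LSC'))", data=df).fit()
        assert res.log2_effect == pytest.approx(fit.params.iloc[1], abs=1e-10)
        assert res.p_raw == pytest.approx(fit.pvalues.iloc[1], abs=1e-10)

    def test_identical_groups_degenerate_null(self):
        m, meta = _two_group_matrix([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        (res,) = fit_bin_model(m, meta, transform="identity")
        assert res.log2_effect == 0.0
        assert res.p_raw == 1.0
        assert not res.degenerate

    def test_zero_variance_with_effect_is_flagged(self):
        m, meta = _two_group_matrix([4.0, 4.0, 4.0], [8.0, 8.0, 8.0])
        (res,) = fit_bin_model(m, meta, transform="identity")
        assert res.degenerate
        assert res.p_raw == 0.0

    def test_permutation_oracle_agreement(self):
        """Two-sided t p-value agrees with a 10,000-draw label-permutation
        test within Monte-Carlo error on near-normal data."""
        rng = np.random.default_rng(3)
        hsc = rng.normal(10.0, 1.0, 6)
        lsc = rng.normal(11.0, 1.0, 6)
        m, meta = _two_group_matrix(hsc, lsc)
        (res,) = fit_bin_model(m, meta, transform="identity")
        pooled = np.concatenate([hsc, lsc])
        obs = abs(res.t_stat)
        count = 0
        n_draws = 10_000
        for _ in range(n_draws):
            perm = rng.permutation(pooled)
            t, _ = sps.ttest_ind(perm[:6], perm[6:], equal_var=True)
            count += abs(t) >= obs - 1e-12
        p_perm = (count + 1) / (n_draws + 1)
        # MC standard error ~ sqrt(p(1-p)/B); allow 4 SE plus permutation discreteness
        se = np.sqrt(p_perm * (1 - p_perm) / n_draws)
        assert abs(res.p_raw - p_perm) < 4 * se + 0.01

    def test_singular_design_rejected(self):
        ids = [f"h{i}" for i in range(4)]
        meta = [SampleMetadata(s, s, s, "HSC", 14) for s in ids]
        m = BinMatrix(
            data=pd.DataFrame({"1.00": [1.0, 2.0, 3.0, 4.0]}, index=ids),
            stage_tag="thresholded",
        )
        with pytest.raises(ValidationError):
            fit_bin_model(m, meta, transform="identity")

    def test_pooled_additive_mode(self, fast_binned):
        from nmrbin.filtering import exclude_bins, threshold_filter

        matrix, meta, _ = fast_binned
        ex, tr = exclude_bins(matrix)
        th, tr = threshold_filter(ex, trace=tr)
        results = fit_bin_model(th, meta, mode="pooled_additive")
        assert {r.week for r in results} == {"pooled"}
        assert len(results) == th.n_bins
        # treatment contrast with intercept + treatment + age: df = n - 3
        assert results[0].df == 24 - 3

    def test_per_week_produces_both_weeks(self, fast_binned):
        from nmrbin.filtering import exclude_bins, threshold_filter

        matrix, meta, _ = fast_binned
        ex, tr = exclude_bins(matrix)
        th, tr = threshold_filter(ex, trace=tr)
        results = fit_bin_model(th, meta)
        assert {r.week for r in results} == {"14", "22"}
        assert len(results) == 2 * th.n_bins


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60)
    )
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60)
    )
    def test_structural_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestAssignTier:
    @pytest.mark.parametrize(
        "q,tier",
        [
            (0.0, "lt_0.05"),
            (0.04, "lt_0.05"),
            (0.05, "lt_0.1"),
            (0.07, "lt_0.1"),
            (0.10, "ns"),
            (0.9, "ns"),
            (1.0, "ns"),
        ],
    )
    def test_boundaries(self, q, tier):
        assert assign_tier(q) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            assign_tier(1.2)
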