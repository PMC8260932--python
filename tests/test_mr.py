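"""Wald-ratio estimation, instrument diagnostics, heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest

import lipidmr as lm
from lipidmr.errors import NestingError, ValidationError, WeakInstrumentError
from lipidmr.mr import STRENGTH_THRESHOLD
from lipidmr.observational import RegressionFit


def _fake_fit(loglik, n=100, k=2):
    return RegressionFit(terms=[f"t{i}" for i in range(k)], beta=np.zeros(k),
                         se=np.ones(k), vcov=np.eye(k), loglik=loglik, n=n,
                         converged=True, family="logistic")


class TestInstrumentStrength:
    def test_zero_improvement_is_weak(self):
        check = lm.instrument_strength(_fake_fit(-50.0, k=3), _fake_fit(-50.0))
        assert check.chi2_improvement == 0.0 and not check.strong

    def test_doubled_loglik_gain(self):
        # a log-likelihood gain of 16.3 doubles to the printed statistic 32.6
        check = lm.instrument_strength(_fake_fit(-100.0 + 16.3, k=3), _fake_fit(-100.0))
        assert check.chi2_improvement == pytest.approx(32.6)
        assert check.strong

    def test_threshold_is_exclusive(self):
        check = lm.instrument_strength(_fake_fit(-100.0 + 5.0, k=3), _fake_fit(-100.0))
        assert check.chi2_improvement == pytest.approx(10.0)
        assert not check.strong  # exactly 10 is not strong

    def test_differing_rows_raise(self):
        with pytest.raises(NestingError):
            lm.instrument_strength(_fake_fit(-10.0, n=50, k=3), _fake_fit(-11.0, n=60))


class TestWaldRatio:
    def test_identity_ratio(self):
        res = lm.wald_ratio(-0.25, 0.01, -0.25, 0.01)
        assert res.beta_iv == pytest.approx(1.0)
        assert res.or_point == pytest.approx(np.e ** 1.0)

    def test_scale_free_for_any_nonzero_slope(self):
        for beta in (-2.0, -0.1, 0.3, 5.0):
            assert lm.wald_ratio(beta, abs(beta) / 50, beta, abs(beta) / 20).beta_iv == 1.0

    def test_delta_method_limit(self):
        # with an exactly-known denominator the SE collapses to se_gy/|beta_gx|
        res = lm.wald_ratio(0.4, 0.1, -0.5, 0.0)
        assert res.se_iv == pytest.approx(0.1 / 0.5)

    def test_printed_stage_estimates_reproduce_mr_or(self):
        """exp(ln 0.82 / ln 0.77) from the printed adjusted stage odds
        ratios lands within 1% of the printed Wald-type OR 2.15."""
        res = lm.wald_ratio(np.log(0.82), 0.084, np.log(0.77), 0.026)
        assert res.or_point == pytest.approx(2.15, rel=0.01)

    def test_zero_denominator_and_guard(self):
        with pytest.raises(ValidationError):
            lm.wald_ratio(0.1, 0.1, 0.0, 0.1)
        with pytest.raises(WeakInstrumentError):
            lm.wald_ratio(0.1, 0.1, 0.05, 0.1)  # |beta_gx|/se = 0.5 < 2
        # override
        assert lm.wald_ratio(0.1, 0.1, 0.05, 0.1, weak_ratio_guard=0).beta_iv == 2.0

    def test_ci_consistent_with_point(self):
        res = lm.wald_ratio(0.3, 0.05, 0.5, 0.04)
        assert res.ci_low < res.or_point < res.ci_high
        assert res.or_point == pytest.approx(np.exp(res.beta_iv))


class TestSeFromCi:
    @pytest.mark.parametrize("ci, expected", [
        ((0.5, 2.0), 0.35365),   # ln 4 / (2 * 1.959964)
        ((1.16, 3.99), 0.31515),
    ])
    def test_log_scale_recovery(self, ci, expected):
        assert lm.se_from_ci(*ci) == pytest.approx(expected, abs=2e-5)

    def test_monotone_in_level(self):
        assert lm.se_from_ci(0.5, 2.0, level=0.99) < lm.se_from_ci(0.5, 2.0, level=0.95)

    def test_validation(self):
        with pytest.raises(ValidationError):
            lm.se_from_ci(2.0, 0.5)


class TestHeterogeneity:
    def test_identical_estimates(self):
        res = lm.heterogeneity_test(0.3, 0.1, 0.3, 0.2)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self):
        fwd = lm.heterogeneity_test(0.1, 0.1, 0.5, 0.2)
        rev = lm.heterogeneity_test(0.5, 0.2, 0.1, 0.1)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p == pytest.approx(rev.p)

    def test_printed_heterogeneity_row(self):
        """Observational OR 1.02 (0.72, 1.44) vs MR OR 2.15 (1.16, 3.99)
        gives the printed p of 0.04."""
        res = lm.heterogeneity_test(
            np.log(1.02), lm.se_from_ci(0.72, 1.44),
            np.log(2.15), lm.se_from_ci(1.16, 3.99),
        )
        assert round(res.p, 2) == 0.04

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValidationError):
            lm.heterogeneity_test(0.1, 0.0, 0.2, 0.1)


class TestMrEstimate:
    def test_effect_scenario_end_to_end(self, effect_cohort):
        res = lm.mr_estimate(effect_cohort, "hdl", "dementia_vs_normal",
                             "pgs_hdl", tier="demographic")
        # the generator's causal log-OR is ln 2.15; one replicate at n=8,000
        # must land within 3 delta-method SEs of it and carry both stage fits
        assert abs(res.beta_iv - np.log(2.15)) < 3 * res.se_iv
        assert res.stage_gx.n == res.stage_gy.n
        assert res.stage_gx.coef("pgs_hdl") < 0  # higher score -> fewer at risk
        assert res.instrument == "pgs_hdl"

    def test_stage_fits_reproduce_strength_check(self, effect_cohort):
        """The attached exposure-stage fit passes the >10 improvement rule
        against an independently refitted reduced model."""
        from lipidmr.mr import _prepare_subset
        from lipidmr.observational import TIER_COVARIATES, fit_logistic
        res = lm.mr_estimate(effect_cohort, "hdl", "cind_vs_normal", "pgs_hdl")
        df = _prepare_subset(effect_cohort, "hdl", "cind_vs_normal")
        reduced = fit_logistic(df, "at_risk", TIER_COVARIATES["demographic"])
        check = lm.instrument_strength(res.stage_gx, reduced, "pgs_hdl")
        assert check.strong
        assert check.chi2_improvement > STRENGTH_THRESHOLD

    def test_permuted_instrument_is_refused(self, effect_cohort):
        rows = effect_cohort.rows.copy()
        rng = np.random.default_rng(0)
        rows["pgs_hdl"] = rng.permutation(rows["pgs_hdl"].to_numpy())
        shuffled = lm.AnalyticCohort(rows=rows, exclusion_log={}, subset_label="all")
        with pytest.raises(WeakInstrumentError):
            lm.mr_estimate(shuffled, "hdl", "dementia_vs_normal", "pgs_hdl")

    def test_constant_instrument_is_refused(self, effect_cohort):
        rows = effect_cohort.rows.copy()
        rows["cetp_dosage"] = 1
        cohort = lm.AnalyticCohort(rows=rows, exclusion_log={}, subset_label="all")
        with pytest.raises(WeakInstrumentError):
            lm.snp_instrument_mode(cohort, "hdl", "dementia_vs_normal")

    def test_snp_mode_equals_pgs_mode_on_same_column(self, effect_cohort):
        rows = effect_cohort.rows.copy()
        rows["pgs_hdl"] = rows["cetp_dosage"].astype(float)
        cohort = lm.AnalyticCohort(rows=rows, exclusion_log={}, subset_label="all")
        via_pgs = lm.mr_estimate(cohort, "hdl", "dementia_vs_normal", "pgs_hdl")
        via_snp = lm.snp_instrument_mode(cohort, "hdl", "dementia_vs_normal")
        assert via_pgs.beta_iv == pytest.approx(via_snp.beta_iv)
        assert via_pgs.se_iv == pytest.approx(via_snp.se_iv)

    def test_snp_instrument_recovers_positive_effect(self, effect_cohort):
        res = lm.snp_instrument_mode(effect_cohort, "hdl", "dementia_vs_normal")
        assert res.beta_iv > 0


class TestPleiotropyAndNegativeControl:
    def test_screen_shape_and_independence(self, null_cohort):
        covs = ["age", "education", "bmi", "drinker", "diabetes"]
        table = lm.pleiotropy_screen(null_cohort, "pgs_hdl", covs)
        assert len(table) == len(covs)
        # instruments are independent of confounders by construction
        assert (np.abs(table["beta"] / table["se"]) < 4).all()

    def test_screen_detects_direct_dependence(self, null_cohort):
        rows = null_cohort.rows.copy()
        rng = np.random.default_rng(1)
        rows["leaky"] = rows["pgs_hdl"] + 0.1 * rng.standard_normal(len(rows))
        cohort = lm.AnalyticCohort(rows=rows, exclusion_log={})
        table = lm.pleiotropy_screen(cohort, "pgs_hdl", ["leaky"])
        assert table.loc[0, "beta"] == pytest.approx(1.0, abs=0.05)

    def test_null_pvalues_are_uniform(self):
        """Instrument-covariate screen p-values are uniform under the null."""
        import scipy.stats as st
        from lipidmr.observational import fit_linear
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(500):
            df = pd.DataFrame({"g": rng.standard_normal(150),
                               "c": rng.standard_normal(150)})
            pvals.append(fit_linear(df, "c", ["g"]).pvalue("g"))
        assert st.kstest(pvals, "uniform").pvalue > 1e-3

    def test_negative_control_null_when_instrument_valid(self, null_cohort):
        fit = lm.negative_control(null_cohort, "hdl")
        lo, hi = fit.conf_int("pgs_hdl")
        assert lo <= 0.0 <= hi
        # restriction really removed at-risk and medicated rows
        sub = null_cohort.rows
        kept = sub[(sub["hdl_status"] == "normal") & (~sub["lipid_med"])]
        assert fit.n <= len(kept)

    def test_negative_control_detects_pleiotropy(self, pleiotropic_cohort):
        fit = lm.negative_control(pleiotropic_cohort, "hdl")
        assert fit.pvalue("pgs_hdl") < 0.01
        assert fit.coef("pgs_hdl") > 0
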