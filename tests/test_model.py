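"""Power-law fit, predictions, decline rates and the bootstrap interval."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amhage import (
    DegenerateDesignError,
    DomainError,
    NonInvertibleModelError,
    PowerFit,
    UsageError,
    apply_loq_policy,
    bootstrap_menopause_ci,
    compare_decline,
    decline_curve,
    fit_power_model,
    predict_age_from_amh,
    predict_amh_at_age,
    predict_menopause_age,
)

AMH_GRID = np.array([0.5, 1.0, 2.0, 4.0, 8.0])


def noisy_fixture(n=20, beta0=38.0, beta1=0.16, sigma=0.1, seed=42):
    rng = np.random.default_rng(seed)
    amh = np.exp(rng.uniform(np.log(0.3), np.log(9.0), n))
    ages = beta0 * amh ** (-beta1) * np.exp(rng.normal(0, sigma, n))
    return ages, amh


class TestFit:
    @given(
        beta0=st.floats(min_value=0.5, max_value=200.0),
        beta1=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_noise_free_recovery_to_1e9_relative(self, beta0, beta1):
        ages = beta0 * AMH_GRID ** (-beta1)
        fit = fit_power_model(ages, AMH_GRID, "pcos")
        assert fit.beta0 == pytest.approx(beta0, rel=1e-9)
        assert fit.beta1 == pytest.approx(beta1, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        ages, amh = noisy_fixture()
        f1 = fit_power_model(ages, amh, "pcos")
        f2 = fit_power_model(3.7 * ages, amh, "pcos")
        assert f2.beta0 == pytest.approx(3.7 * f1.beta0, rel=1e-12)
        assert f2.beta1 == pytest.approx(f1.beta1, rel=1e-12)

    def test_matches_profile_grid_search_oracle(self):
        # brute-force SSE minimization over beta1 with the intercept profiled out
        ages, amh = noisy_fixture()
        x, y = np.log(amh), np.log(ages)
        beta1_grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        sse = np.array(
            [np.sum((y - np.mean(y + b1 * x) + b1 * x) ** 2) for b1 in beta1_grid]
        )
        best = beta1_grid[np.argmin(sse)]
        fit = fit_power_model(ages, amh, "pcos")
        assert abs(fit.beta1 - best) <= 1e-4

        # OLS solution beats every point of a coarse 2-D (ln beta0, beta1) grid
        resid = y - (math.log(fit.beta0) - fit.beta1 * x)
        sse_ols = resid @ resid
        for lb0 in np.linspace(math.log(fit.beta0) - 0.5, math.log(fit.beta0) + 0.5, 41):
            for b1 in np.linspace(0.0, 1.0, 101):
                r = y - (lb0 - b1 * x)
                assert sse_ols <= r @ r + 1e-12

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        ages, amh = noisy_fixture(seed=11)
        fit = fit_power_model(ages, amh, "pcos")
        res = sm.OLS(np.log(ages), sm.add_constant(np.log(amh))).fit()
        assert fit.log_beta0 == pytest.approx(res.params[0], rel=1e-10)
        assert fit.beta1 == pytest.approx(-res.params[1], rel=1e-10)
        assert fit.r_squared == pytest.approx(res.rsquared, rel=1e-10)
        assert fit.residual_sd == pytest.approx(np.sqrt(res.ssr / res.df_resid), rel=1e-10)

    def test_all_equal_amh_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_power_model([30, 31, 32], [2.0, 2.0, 2.0], "pcos")

    def test_two_distinct_amh_values_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_power_model([30, 31, 32, 33], [1.0, 1.0, 2.0, 2.0], "pcos")

    def test_nonpositive_amh_is_domain_error_mentioning_policy(self):
        with pytest.raises(DomainError, match="limit-of-quantification"):
            fit_power_model([30, 31, 32], [1.0, 0.0, 2.0], "pcos")

    def test_loq_policy_replaces_below_limit_with_half(self):
        out = apply_loq_policy([0.0, 0.05, 0.5], loq=0.1)
        assert out.tolist() == [0.05, 0.05, 0.5]

    def test_log_beta0_is_exactly_ln_beta0(self):
        fit = PowerFit.from_coefficients(41.41, 0.17, "pcos")
        assert fit.log_beta0 == math.log(fit.beta0)


class TestPredictions:
    def test_group2_printed_coefficients_give_45_2(self, printed_fits):
        age = predict_age_from_amh(printed_fits["eumenorrheic"], 0.2)
        assert round(age, 1) == 45.2

    def test_group1_printed_coefficients_give_54_4(self, printed_fits):
        # direct evaluation of the printed formula with printed coefficients
        age = predict_age_from_amh(printed_fits["pcos"], 0.2)
        assert round(age, 1) == 54.4

    def test_unit_amh_returns_beta0_exactly(self, printed_fits):
        for fit in printed_fits.values():
            assert predict_age_from_amh(fit, 1.0) == fit.beta0

    def test_table_self_consistency_group2(self):
        # beta0 implied by the printed prediction and exponent
        assert 35.4 <= 45.2 / 0.2 ** (-0.15) <= 35.6

    def test_inverse_at_beta0_is_unit_amh(self, printed_fits):
        fit = printed_fits["pcos"]
        assert predict_amh_at_age(fit, fit.beta0) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("amh", [0.2, 1.0, 4.95])
    def test_inversion_round_trip(self, printed_fits, amh):
        fit = printed_fits["eumenorrheic"]
        back = predict_amh_at_age(fit, predict_age_from_amh(fit, amh))
        assert back == pytest.approx(amh, rel=1e-9)

    def test_inverse_of_printed_worked_example(self, printed_fits):
        amh = predict_amh_at_age(printed_fits["eumenorrheic"], 45.2)
        assert round(amh, 1) == 0.2

    def test_beta1_zero_is_not_invertible(self):
        fit = PowerFit.from_coefficients(40.0, 0.0, "pcos")
        with pytest.raises(NonInvertibleModelError):
            predict_amh_at_age(fit, 40.0)

    def test_menopause_prediction_records_cutoff(self, printed_fits):
        p = predict_menopause_age(printed_fits["eumenorrheic"])
        assert p.cutoff == 0.2
        assert p.predicted_age == predict_age_from_amh(printed_fits["eumenorrheic"], 0.2)

    def test_unit_cutoff_returns_beta0(self, printed_fits):
        p = predict_menopause_age(printed_fits["pcos"], cutoff=1.0)
        assert p.predicted_age == printed_fits["pcos"].beta0

    def test_menopause_age_strictly_decreasing_in_cutoff(self, printed_fits):
        cutoffs = np.linspace(0.05, 2.0, 40)
        ages = [
            predict_menopause_age(printed_fits["pcos"], c).predicted_age for c in cutoffs
        ]
        assert all(a > b for a, b in zip(ages, ages[1:]))

    def test_nonpositive_inputs_are_domain_errors(self, printed_fits):
        fit = printed_fits["pcos"]
        with pytest.raises(DomainError):
            predict_age_from_amh(fit, 0.0)
        with pytest.raises(DomainError):
            predict_menopause_age(fit, cutoff=-0.2)


class TestDeclineCurve:
    def test_rates_all_negative(self, printed_fits):
        curve = decline_curve(printed_fits["pcos"], 30, 55, 51)
        assert np.all(curve.rates < 0)
        assert np.all(curve.amh_values > 0)

    def test_analytic_rate_matches_finite_difference(self, printed_fits):
        fit = printed_fits["eumenorrheic"]
        rng = np.random.default_rng(0)
        ages = rng.uniform(30, 55, 10)
        h = 1e-5
        fd = (predict_amh_at_age(fit, ages + h) - predict_amh_at_age(fit, ages - h)) / (2 * h)
        curve_rates = -predict_amh_at_age(fit, ages) / (fit.beta1 * ages)
        assert curve_rates == pytest.approx(fd, rel=1e-6)

    def test_invalid_grid_is_usage_error(self, printed_fits):
        with pytest.raises(UsageError):
            decline_curve(printed_fits["pcos"], 40, 30, 10)
        with pytest.raises(UsageError):
            decline_curve(printed_fits["pcos"], 30, 40, 1)


class TestCompareDecline:
    def test_identical_fits_tie_everywhere(self, printed_fits):
        fit = printed_fits["pcos"]
        cmp = compare_decline(fit, fit, np.linspace(30, 45, 16))
        assert cmp.fraction_tie == 1.0
        assert set(cmp.table["faster"]) == {"tie"}

    def test_equal_beta1_ordering_is_closed_form(self):
        # same exponent: |rate| ratio is (beta0_a/beta0_b)^(1/beta1) at every age,
        # so the smaller beta0 loses everywhere
        a = PowerFit.from_coefficients(30.0, 0.15, "pcos")
        b = PowerFit.from_coefficients(40.0, 0.15, "eumenorrheic")
        cmp = compare_decline(a, b, np.linspace(30, 45, 31))
        assert cmp.fraction_b == 1.0

    def test_printed_fits_fractions_sum_to_one(self, printed_fits):
        cmp = compare_decline(
            printed_fits["pcos"], printed_fits["eumenorrheic"], np.linspace(30, 45, 151)
        )
        assert cmp.fraction_a + cmp.fraction_b + cmp.fraction_tie == pytest.approx(1.0)
        assert len(cmp.table) == 151

    def test_eumenorrheic_declines_faster_over_study_ages(self, printed_fits):
        # per-age verdict with the printed coefficients over ages 30-45
        cmp = compare_decline(
            printed_fits["eumenorrheic"], printed_fits["pcos"], np.linspace(30, 45, 151)
        )
        rates_e = np.abs(cmp.table["rate_a"].to_numpy())
        rates_p = np.abs(cmp.table["rate_b"].to_numpy())
        assert cmp.fraction_a == pytest.approx(np.mean(rates_e > rates_p))


class TestBootstrap:
    def test_same_seed_gives_identical_interval(self):
        ages, amh = noisy_fixture(n=40)
        p1 = bootstrap_menopause_ci(ages, amh, "pcos", n_boot=200, seed=5)
        p2 = bootstrap_menopause_ci(ages, amh, "pcos", n_boot=200, seed=5)
        assert (p1.ci_low, p1.ci_high) == (p2.ci_low, p2.ci_high)

    def test_noise_free_data_gives_zero_width_interval(self):
        amh = np.array([0.5, 1.0, 2.0, 4.0, 8.0] * 4)
        ages = 40.0 * amh ** (-0.1)
        p = bootstrap_menopause_ci(ages, amh, "pcos", n_boot=200, seed=1)
        assert p.ci_high - p.ci_low == pytest.approx(0.0, abs=1e-9)
        assert p.ci_low <= p.predicted_age <= p.ci_high

    def test_interval_brackets_point_estimate(self):
        ages, amh = noisy_fixture(n=30, sigma=0.3, seed=9)
        p = bootstrap_menopause_ci(ages, amh, "pcos", n_boot=300, seed=2)
        assert p.ci_low <= p.predicted_age <= p.ci_high

    def test_parameter_validation(self):
        ages, amh = noisy_fixture()
        with pytest.raises(UsageError):
            bootstrap_menopause_ci(ages, amh, "pcos", n_boot=50)
        with pytest.raises(UsageError):
            bootstrap_menopause_ci(ages, amh, "pcos", level=1.5)
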