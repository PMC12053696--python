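"""Gamma age models, walking-speed model, ZIBB disability, NB hazard model."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, gammaln, logsumexp

from octoclock import (
    MCMCConfig,
    fit_binary_outcome,
    fit_di,
    fit_gamma_age,
    fit_speed,
    predict_age,
    zibb_loglik,
)


class TestPredictAge:
    def test_population_body_age_worked_example(self):
        assert predict_age(3.78, 0.12, 9, decimals=2) == 129.02

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(-3, 6), b=st.floats(-2, 2), x=st.floats(-10, 12))
    def test_agrees_with_hand_calculation(self, a, b, x):
        expected = math.exp(a + b * x)
        got = predict_age(a, b, x)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_multi_predictor_form(self):
        assert predict_age(1.0, [0.5, -0.25], [2.0, 4.0]) == pytest.approx(
            math.exp(1.0 + 1.0 - 1.0)
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            predict_age(np.inf, 0.1, 1.0)


def _betabinom_logpmf_oracle(y, n, a, b):
    """Independent beta-binomial log-pmf via the explicit beta-function form."""
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


class TestZibbLoglik:
    def test_reduces_to_beta_binomial_when_pi_zero(self):
        y = np.arange(0, 48)
        got = zibb_loglik(y, 47, mu=0.2, phi=8.0, pi=0.0)
        want = _betabinom_logpmf_oracle(y, 47, 0.2 * 8.0, 0.8 * 8.0)
        assert np.allclose(got, want)

    def test_degenerate_full_inflation(self):
        assert zibb_loglik(0, 47, 0.1, 5.0, 1.0) == pytest.approx(0.0)
        assert zibb_loglik(3, 47, 0.1, 5.0, 1.0) == -np.inf

    def test_normalizes_by_enumeration(self):
        rng = np.random.default_rng(0)
        y = np.arange(0, 48)
        for _ in range(20):
            mu, phi, pi = rng.uniform(0.02, 0.9), rng.uniform(0.5, 60), rng.uniform(0, 1)
            total = logsumexp(zibb_loglik(y, 47, mu, phi, pi))
            assert total == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(y=-1, n=47, mu=0.1, phi=5, pi=0.1),
            dict(y=48, n=47, mu=0.1, phi=5, pi=0.1),
            dict(y=1, n=47, mu=1.2, phi=5, pi=0.1),
            dict(y=1, n=47, mu=0.1, phi=-1, pi=0.1),
            dict(y=1, n=47, mu=0.1, phi=5, pi=1.5),
        ],
    )
    def test_domain_violations(self, kwargs):
        with pytest.raises(ValueError):
            zibb_loglik(**kwargs)


class TestGammaAge:
    def test_parameter_recovery_at_reported_scale(self):
        """Simulated from the population-level mapping (intercept 3.78, slope
        0.12): the posterior must recover both coefficients tightly."""
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 11, 2000)
        shape = 30.0
        age = rng.gamma(shape, np.exp(3.78 + 0.12 * x) / shape)
        fit = fit_gamma_age(age, x, seed=1)
        assert abs(fit.intercept.mean() - 3.78) < 0.05
        assert abs(fit.slopes[:, 0].mean() - 0.12) < 0.01

    def test_constant_predictor_gives_null_slope(self):
        rng = np.random.default_rng(1)
        age = rng.gamma(20.0, 70.0 / 20.0, 800)
        fit = fit_gamma_age(age, np.full(800, 5.0), seed=2, n_steps=1200)
        med, lo, hi = fit.coefficient_summary()
        assert lo < 0 < hi

    def test_predictions_positive_and_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 500)
        age = rng.gamma(25.0, np.exp(3.5 + 0.1 * x) / 25.0)
        fit = fit_gamma_age(age, x, seed=3, n_steps=1200)
        grid = np.linspace(0, 10, 7)
        pred = fit.predict(grid)
        assert np.all(pred > 0) and np.all(np.diff(pred) > 0)

    def test_nonpositive_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_age(np.array([50.0, -1.0]), np.array([1.0, 2.0]))


class TestSpeed:
    def test_slope_recovery_at_reported_scale(self):
        """The generating decline of 0.06 m/s per clock unit (the reported
        order of magnitude) must be recovered within 0.01."""
        rng = np.random.default_rng(0)
        clock = rng.uniform(2, 11, 1500)
        h = rng.normal(1.7, 0.09, 1500)
        speed = np.clip(
            1.5 - 0.06 * clock + 0.3 * (h - 1.7) + 0.1 * rng.standard_normal(1500),
            0.05, None,
        )
        fit = fit_speed(speed, clock, h, seed=1)
        assert abs(fit.clock_slope.mean() + 0.06) < 0.01
        # homoscedastic truth: sigma-model slope centered at zero
        lo, hi = np.quantile(fit.sigma_slope, [0.025, 0.975])
        assert lo < 0 < hi
        # predictions decrease stochastically in the clock
        pred_lo = fit.predict(np.full(5, 3.0), np.full(5, 1.7))
        pred_hi = fit.predict(np.full(5, 9.0), np.full(5, 1.7))
        assert pred_lo.mean() > pred_hi.mean()

    def test_height_required(self):
        with pytest.raises(ValueError, match="height"):
            fit_speed(np.array([1.0, 1.1]), np.array([3.0, 4.0]), None)


class TestDisabilityModel:
    def test_bounds_and_rough_recovery(self):
        rng = np.random.default_rng(0)
        n = 47
        pi, mu, phi = 0.3, 0.1, 10.0
        infl = rng.random(600) < pi
        y = rng.binomial(n, rng.beta(mu * phi, (1 - mu) * phi, 600))
        y[infl] = 0
        fit = fit_di(y, n, sampler=MCMCConfig(seed=1, n_warmup=500, n_draws=700))
        di = fit.predict_proportion()
        assert np.all((di > 0) & (di < 1))
        lo, hi = np.quantile(fit.pi, [0.05, 0.95])
        assert lo < pi < hi
        lo, hi = np.quantile(expit(fit.mu_intercept), [0.05, 0.95])
        assert lo < mu < hi

    def test_homogeneous_cohort_gives_near_constant_di(self):
        rng = np.random.default_rng(1)
        n = 47
        y = rng.binomial(n, rng.beta(0.1 * 20, 0.9 * 20, 400))
        groups = np.repeat(np.arange(100), 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_di(y, n, group_ids=groups,
                         sampler=MCMCConfig(seed=2, n_warmup=400, n_draws=500))
        di = fit.predict_proportion(group_codes=np.arange(100))
        assert di.std() < 0.03

    def test_all_zero_counts_flagged_not_fatal(self):
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_di(np.zeros(60, dtype=int), 47,
                         sampler=MCMCConfig(seed=3, n_warmup=300, n_draws=300))
        assert fit.all_zero_flag
        assert np.all(fit.predict_proportion() < 0.05)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fit_di(np.array([50]), 47)


class TestBinaryOutcome:
    def _simulate(self, rng, loghr, n=700):
        clock = rng.uniform(2, 11, n)
        expo = np.full(n, 2.0)
        y = rng.poisson(0.002 * np.exp(loghr * clock) * expo)
        return y, expo, clock

    def test_hazard_ratio_recovery(self):
        rng = np.random.default_rng(0)
        y, expo, clock = self._simulate(rng, np.log(1.8), n=900)
        fit = fit_binary_outcome(y, expo, clock, sampler=MCMCConfig(seed=1))
        hr, lo, hi = fit.hr_summary()
        assert 1.5 < hr < 2.2

    def test_null_loghr_interval_covers_one(self):
        rng = np.random.default_rng(1)
        clock = rng.uniform(2, 11, 700)
        expo = np.full(700, 2.0)
        y = rng.poisson(0.05 * expo)
        fit = fit_binary_outcome(y, expo, clock, sampler=MCMCConfig(seed=2))
        _, lo, hi = fit.hr_summary()
        assert lo < 1 < hi

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        y, expo, clock = self._simulate(rng, np.log(1.5))
        f1 = fit_binary_outcome(y, expo, clock, sampler=MCMCConfig(seed=3))
        f2 = fit_binary_outcome(y, 2 * expo, clock, sampler=MCMCConfig(seed=3))
        assert abs(f1.hr_summary()[0] - f2.hr_summary()[0]) < 0.08
        # intercept absorbs the doubled exposure
        assert abs((f1.intercept.mean() - f2.intercept.mean()) - np.log(2)) < 0.1

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning, match="no events"):
            fit = fit_binary_outcome(
                np.zeros(50, dtype=int), np.ones(50), np.linspace(2, 9, 50),
                sampler=MCMCConfig(seed=4, n_warmup=200, n_draws=200),
            )
        assert fit.degenerate
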