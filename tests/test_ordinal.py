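"""Cumulative ordinal likelihood, monotonic effects, sampling and prediction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from octoclock import (
    CumulativeSpec,
    MCMCConfig,
    MonotonicEffect,
    OrdinalFit,
    category_probs,
    default_codex,
    fit_ordinal,
    monotonic_contribution,
)
from octoclock.ordinal import DegenerateOutcomeError
from octoclock.simulate import simulate_cumulative_frame


class TestMonotonicContribution:
    def test_reference_level_is_zero(self):
        eff = MonotonicEffect(b_max=0.7, zeta=(0.3, 0.7))
        assert monotonic_contribution(1, eff) == 0.0

    def test_top_level_is_total_effect(self):
        # e.g. a binary condition whose presence contributes 0.32 on the
        # latent scale contributes exactly that at its top level
        eff = MonotonicEffect(b_max=0.32, zeta=(1.0,))
        assert monotonic_contribution(2, eff) == pytest.approx(0.32)

    def test_partial_sum(self):
        eff = MonotonicEffect(b_max=1.0, zeta=(0.25, 0.75))
        assert monotonic_contribution(2, eff) == pytest.approx(0.25)

    def test_out_of_range_level(self):
        eff = MonotonicEffect(b_max=1.0, zeta=(1.0,))
        with pytest.raises(ValueError):
            monotonic_contribution(3, eff)

    @settings(max_examples=200, derandomize=True)
    @given(
        raw=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
        b=st.floats(0.0, 5.0),
    )
    def test_nondecreasing_in_level(self, raw, b):
        zeta = np.asarray(raw) / np.sum(raw)
        eff = MonotonicEffect(b_max=b, zeta=tuple(zeta))
        vals = [monotonic_contribution(k, eff) for k in range(1, len(zeta) + 2)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_invalid_simplex(self):
        with pytest.raises(ValueError):
            MonotonicEffect(b_max=1.0, zeta=(0.5, 0.6))


class TestCategoryProbs:
    def test_two_category_symmetry(self):
        spec = CumulativeSpec(2, thresholds=np.array([0.0]))
        assert category_probs(0.0, spec) == pytest.approx([0.5, 0.5])

    def test_matches_cdf_differences(self):
        tau = np.array([-1.0, 0.0, 1.0])
        spec = CumulativeSpec(4, thresholds=tau)
        eta = 0.7
        expected = np.diff(np.concatenate([[0], expit(tau - eta), [1]]))
        assert category_probs(eta, spec) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(
        eta=st.floats(-8, 8),
        raw=st.lists(st.floats(-4, 4), min_size=1, max_size=10, unique=True),
    )
    def test_rows_sum_to_one(self, eta, raw):
        tau = np.sort(np.asarray(raw))
        if np.any(np.diff(tau) <= 1e-9):
            return
        spec = CumulativeSpec(len(tau) + 1, thresholds=tau)
        assert category_probs(eta, spec).sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CumulativeSpec(3, thresholds=np.array([1.0, 0.0]))

    def test_spec_from_default_codex_has_13_thresholds(self):
        spec = CumulativeSpec.from_codex(default_codex())
        assert spec.n_thresholds == 13 and spec.n_categories == 14


class TestFitOrdinal:
    def test_intercept_only_threshold_recovery(self):
        truth = [-1.0, 0.5, 2.0]
        frame, _ = simulate_cumulative_frame(
            400, 3, [2], thresholds=truth, b_max=[0.0], beta_time=0.0,
            sigma_u=0.4, seed=7,
        )
        fit = fit_ordinal(frame, monotonic=(), linear=(),
                          sampler=MCMCConfig(seed=1, n_warmup=800, n_draws=1500))
        assert fit.converged
        med = np.median(fit.thresholds, axis=0)
        assert np.all(np.abs(med - truth) < 0.2)

    def test_binary_reduction_matches_bayesian_logistic(self):
        """With one binary disease, two outcome categories and no random
        intercepts, the cumulative-monotonic model reduces to logistic
        regression; its posterior must match an independent ensemble fit."""
        frame, _ = simulate_cumulative_frame(
            500, 2, [2], thresholds=[0.3], b_max=[1.0], beta_time=0.0,
            sigma_u=0.0, seed=9,
        )
        fit = fit_ordinal(frame, monotonic=("d01",), linear=(), with_groups=False,
                          sampler=MCMCConfig(seed=3, n_warmup=600, n_draws=1200))

        import emcee

        y = frame.outcome.astype(float)
        x = (frame.data["d01"].to_numpy() == 2).astype(float)

        def logpost(theta):
            # intercept = -tau under the cumulative convention
            a, b = theta
            eta = a + b * x
            lp = -a**2 / (2 * 2.5**2) - b**2 / (2 * 2**2)
            return lp + float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        rng = np.random.default_rng(11)
        sampler = emcee.EnsembleSampler(16, 2, logpost)
        p0 = 0.1 * rng.standard_normal((16, 2))
        sampler.run_mcmc(p0, 1500, progress=False, skip_initial_state_check=True)
        ref = sampler.get_chain(discard=500, flat=True)

        assert abs(np.mean(fit.b["d01"]) - ref[:, 1].mean()) < 0.12
        assert abs(np.mean(-fit.thresholds[:, 0]) - ref[:, 0].mean()) < 0.12

    def test_degenerate_outcome_raises(self):
        frame, _ = simulate_cumulative_frame(
            30, 2, [2], thresholds=[-15.0], b_max=[0.0], beta_time=0.0,
            sigma_u=0.0, seed=2,
        )
        assert len(np.unique(frame.outcome)) == 1
        with pytest.raises(DegenerateOutcomeError):
            fit_ordinal(frame)

    def test_zero_variance_predictor_dropped(self, small_fit):
        frame, _, _ = small_fit
        data = frame.data.copy()
        data["flat"] = 1
        frame2 = type(frame)(
            data=data,
            disease_cols=frame.disease_cols + ("flat",),
            n_levels={**frame.n_levels, "flat": 3},
            n_categories=frame.n_categories,
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_ordinal(frame2, sampler=MCMCConfig(seed=1, n_warmup=100, n_draws=100))
        assert fit.dropped_diseases == ("flat",)
        assert "flat" not in fit.b

    def test_individual_permutation_leaves_posterior_unchanged(self):
        frame, _ = simulate_cumulative_frame(
            120, 3, [3], thresholds=[-0.5, 1.0], b_max=[1.0], beta_time=0.0,
            sigma_u=0.3, seed=13,
        )
        cfg = MCMCConfig(seed=5, n_warmup=500, n_draws=800)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_a = fit_ordinal(frame, sampler=cfg)
            perm = frame.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
            frame_b = type(frame)(
                data=perm, disease_cols=frame.disease_cols,
                n_levels=frame.n_levels, n_categories=frame.n_categories,
            )
            fit_b = fit_ordinal(frame_b, sampler=cfg)
        assert abs(np.mean(fit_a.b["d01"]) - np.mean(fit_b.b["d01"])) < 0.12


class TestPosteriorPrediction:
    def test_mean_prediction_within_category_range(self, small_fit):
        frame, _, fit = small_fit
        pred = fit.predict(frame)
        K = fit.spec.n_thresholds
        assert np.all(pred >= 0) and np.all(pred <= K)

    def test_extreme_severities_order_predictions(self, small_fit):
        frame, _, fit = small_fit
        top = frame.data.iloc[[0]].copy()
        bottom = frame.data.iloc[[0]].copy()
        for d in fit.diseases:
            top[d] = fit.n_levels[d]
            bottom[d] = 1
        top["individual_id"] = bottom["individual_id"] = "unseen"
        hi = fit.predict(top, group_mode="population", seed=1)[0]
        lo = fit.predict(bottom, group_mode="population", seed=1)[0]
        assert hi > lo

    def test_analytic_expectation_matches_sampled_categories(self, small_fit):
        """Per-row posterior-mean category from the analytic probabilities must
        agree with a brute-force categorical sampler over the same draws."""
        frame, _, fit = small_fit
        sub = frame.data.iloc[:40]
        analytic = fit.predict(sub, seed=0)
        reps = fit.sample_replicates(sub, n_rep=4000, seed=0)
        sampled = reps.mean(axis=0)
        # MC error of a mean over 4000 categorical draws in [0, 3]
        assert np.max(np.abs(analytic - sampled)) < 0.15

    def test_unseen_disease_column_rejected(self, small_fit):
        frame, _, fit = small_fit
        with pytest.raises(Exception, match="d01"):
            fit.predict(frame.data.drop(columns=["d01"]))

    def test_severity_outside_fitted_range_rejected(self, small_fit):
        frame, _, fit = small_fit
        bad = frame.data.copy()
        bad.loc[bad.index[0], "d02"] = 5  # d02 has 2 levels
        with pytest.raises(Exception, match="range"):
            fit.predict(bad)

    def test_save_load_round_trip(self, small_fit, tmp_path):
        frame, _, fit = small_fit
        path = tmp_path / "fit.npz"
        fit.save(path)
        back = OrdinalFit.load(path)
        assert np.allclose(back.b["d01"], fit.b["d01"])
        assert np.allclose(back.predict(frame, seed=3), fit.predict(frame, seed=3))
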