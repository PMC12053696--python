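"""Synthetic-cohort generator: determinism, aging structure, outcome couplings."""

import numpy as np
import pandas as pd
import pytest

from octoclock import SimulationConfig, compute_bodn, generate_cohort
from octoclock.io import write_panel
from octoclock.simulate import simulate_cumulative_frame


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_individuals=1),
            dict(n_visits=1),
            dict(di_trials=0),
            dict(zibb_pi=1.5),
            dict(zibb_phi=-1.0),
            dict(visit_spacing=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_individuals=50, seed=9, zibb_pi=0.2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestGenerateCohort:
    def test_byte_identical_output_under_fixed_seed(self, small_codex, tmp_path):
        cfg = SimulationConfig(n_individuals=60, n_visits=3, seed=4)
        paths = [tmp_path / "a.csv", tmp_path / "b.csv"]
        for p in paths:
            panel, _ = generate_cohort(cfg, small_codex)
            write_panel(panel, p, small_codex)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_mean_bodn_strictly_increasing_across_visits(self, small_codex):
        cfg = SimulationConfig(n_individuals=300, n_visits=4, seed=1,
                               mortality_base_hazard=0.0)
        panel, _ = generate_cohort(cfg, small_codex)
        means = (
            compute_bodn(panel, small_codex)
            .groupby(panel["visit_index"])
            .mean()
        )
        assert np.all(np.diff(means.to_numpy()) > 0)

    def test_severities_monotone_within_individual(self, small_codex, small_cohort):
        panel, _ = small_cohort
        for d in small_codex.disease_names:
            diffs = panel.sort_values(["individual_id", "visit_index"]).groupby(
                "individual_id"
            )[d].diff().dropna()
            assert (diffs >= 0).all()

    def test_bodn_variance_increases_with_age_band(self):
        """Default configuration: baseline BODN grows more heterogeneous with
        age band, the qualitative pattern of aging cohorts."""
        from octoclock import default_codex

        codex = default_codex()
        variances = []
        for seed in (0, 1):
            cfg = SimulationConfig(n_individuals=600, n_visits=2, seed=seed)
            panel, _ = generate_cohort(cfg, codex)
            base = panel[panel.visit_index == 1].copy()
            base["bodn"] = compute_bodn(base, codex)
            bands = pd.cut(base.chronological_age, [40, 50, 60, 70, 85])
            variances.append(
                base.groupby(bands, observed=True)["bodn"].var().to_numpy()
            )
        v = np.mean(variances, axis=0)
        assert np.all(np.diff(v) > 0)

    def test_homogeneous_cohort_shares_trajectory(self, small_codex):
        cfg = SimulationConfig(
            n_individuals=400, n_visits=3, seed=2, latent_rate_sd=0.0,
            severity_step_logits=(-3.5,) * 6, mortality_base_hazard=0.0,
        )
        panel, truth = generate_cohort(cfg, small_codex)
        assert set(truth.latent_rate.values()) == {1.0}
        # two random halves follow the same expected trajectory
        bodn = compute_bodn(panel, small_codex)
        last = panel.visit_index == 3
        ids = panel.individual_id[last].to_numpy()
        vals = bodn[last].to_numpy()
        half = np.array([int(i[1:]) < 200 for i in ids])
        se = np.sqrt(vals.var() * (1 / half.sum() + 1 / (~half).sum()))
        assert abs(vals[half].mean() - vals[~half].mean()) < 3 * se

    def test_walking_speed_declines_with_burden(self, small_cohort):
        panel, truth = small_cohort
        tc = np.array([
            truth.true_clock[i][v - 1]
            for i, v in zip(panel.individual_id, panel.visit_index)
        ])
        slope = np.polyfit(tc, panel.walking_speed, 1)[0]
        assert -0.08 < slope < -0.02  # generating value -0.05 m/s per unit

    def test_disability_counts_match_zibb_moments(self, small_codex):
        """Homogeneous cohort at n=5000: empirical disability-count moments
        match the zero-inflated beta-binomial's analytic moments."""
        cfg = SimulationConfig(
            n_individuals=5000, n_visits=2, seed=3, latent_rate_sd=0.0,
            di_mu_slope=0.0, di_mu_intercept=-2.0, zibb_pi=0.25, zibb_phi=8.0,
            mortality_base_hazard=0.0,
        )
        panel, _ = generate_cohort(cfg, small_codex)
        y = panel[panel.visit_index == 1]["disability_events"].to_numpy()
        n, mu, phi, pi = 47, 1 / (1 + np.exp(2.0)), 8.0, 0.25
        mean_bb = n * mu
        var_bb = n * mu * (1 - mu) * (n + phi) / (phi + 1)
        mean_z = (1 - pi) * mean_bb
        var_z = (1 - pi) * (var_bb + mean_bb**2) - mean_z**2
        assert y.mean() == pytest.approx(mean_z, rel=0.05)
        assert y.var() == pytest.approx(var_z, rel=0.10)

    def test_mortality_null_kaplan_meier(self, small_codex):
        """With a zero clock log-hazard, survival is independent of the latent
        clock: the logrank test is non-significant in >= 18 of 20 seeds."""
        from lifelines.statistics import logrank_test

        passes = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_individuals=500, n_visits=4, seed=seed,
                mortality_clock_loghr=0.0, mortality_base_hazard=0.04,
            )
            panel, truth = generate_cohort(cfg, small_codex)
            first = panel.groupby("individual_id").first()
            tc0 = np.array([truth.true_clock[i][0] for i in first.index])
            hi = tc0 > np.median(tc0)
            res = logrank_test(
                first.censor_time[hi], first.censor_time[~hi],
                first.death_indicator[hi], first.death_indicator[~hi],
            )
            passes += res.p_value > 0.01
        assert passes >= 18

    def test_ground_truth_is_complete_sidecar(self, small_codex, small_cohort):
        panel, truth = small_cohort
        assert set(truth.latent_rate) == set(panel.individual_id.unique())
        assert set(truth.b_max_true) == set(small_codex.disease_names)
        for z in truth.zeta_true.values():
            assert sum(z) == pytest.approx(1.0) and min(z) >= 0
        assert "b_max_true" not in panel.columns  # never merged into the panel

    def test_ground_truth_json_round_trip(self, small_cohort, tmp_path):
        _, truth = small_cohort
        from octoclock import GroundTruth

        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.latent_rate == truth.latent_rate
        assert back.b_max_true == truth.b_max_true


class TestSimulateCumulativeFrame:
    def test_deterministic_and_in_range(self):
        a, _ = simulate_cumulative_frame(
            50, 3, [3, 2], thresholds=[-1, 0, 1], b_max=[1.0, -0.5], seed=5
        )
        b, _ = simulate_cumulative_frame(
            50, 3, [3, 2], thresholds=[-1, 0, 1], b_max=[1.0, -0.5], seed=5
        )
        assert a.data.equals(b.data)
        assert a.outcome.min() >= 0 and a.outcome.max() <= 3

    def test_ground_truth_records_generating_parameters(self):
        _, truth = simulate_cumulative_frame(
            20, 2, [3], thresholds=[-1, 1], b_max=[0.7],
            zeta=[[0.2, 0.8]], beta_time=0.3, sigma_u=0.6, seed=6,
        )
        assert truth.b_max_true == {"d01": 0.7}
        assert truth.zeta_true == {"d01": [0.2, 0.8]}
        assert truth.sigma_u_true == 0.6 and truth.beta_time_true == 0.3

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            simulate_cumulative_frame(10, 2, [2], thresholds=[1, 0], b_max=[0.0])
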