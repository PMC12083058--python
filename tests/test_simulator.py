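"""Monte-Carlo checks of the cohort generator against closed forms and the
deterministic model mathematics (simulator and model core as mutual oracles)."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from helpers import constant_hazard_params, toy_params
from jmsched import (SimulationConfig, SubjectTruth, calibrate_weibull,
                     generate_dataset, observe_biomarkers, overall_survival,
                     sample_event_time)
from jmsched.model_core import CauseSpec, hazard_batch
from jmsched.simulator import (CalibrationError, draw_subjects,
                               sample_event_times)
from jmsched import _engine


class TestDrawSubject:
    def test_zero_covariance_gives_zero_effects(self, rng):
        p = constant_hazard_params([1.0], re_covariance=np.zeros((4, 4)))
        subs = draw_subjects(p, SimulationConfig(), rng, 50)
        assert all(np.all(s.random_effects == 0) for s in subs)

    def test_sample_covariance_matches_d(self, published_params, rng):
        subs = draw_subjects(published_params, SimulationConfig(), rng, 10_000)
        B = np.stack([s.random_effects for s in subs])
        S = np.cov(B.T)
        D = published_params.re_covariance
        assert np.linalg.norm(S - D) / np.linalg.norm(D) < 0.05

    def test_maggic_moments(self, published_params, rng):
        cfg = SimulationConfig(maggic_mean=22.0, maggic_sd=6.0)
        subs = draw_subjects(published_params, cfg, rng, 10_000)
        m = np.array([s.baseline_covariates[0] for s in subs])
        assert abs(m.mean() - 22.0) < 3 * 6.0 / np.sqrt(10_000)
        assert abs(m.std() - 6.0) < 0.2


class TestEventTimes:
    def test_exponential_mean(self, rng):
        p = constant_hazard_params([1.0], re_covariance=np.zeros((4, 4)))
        cfg = SimulationConfig(censor_time=1e6)
        subs = draw_subjects(p, cfg, rng, 4000)
        sample_event_times(p, subs, cfg, rng)
        T = np.array([s.true_event_time for s in subs])
        assert np.all(np.array([s.true_cause for s in subs]) == 1)
        assert abs(T.mean() - 1.0) < 3 / np.sqrt(4000)

    def test_equal_hazards_split_causes_evenly(self, rng):
        p = constant_hazard_params([0.5, 0.5], re_covariance=np.zeros((4, 4)))
        cfg = SimulationConfig(censor_time=1e6)
        subs = draw_subjects(p, cfg, rng, 10_000)
        sample_event_times(p, subs, cfg, rng)
        frac1 = np.mean([s.true_cause == 1 for s in subs])
        assert abs(frac1 - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_vanishing_hazard_always_censors(self, rng):
        p = constant_hazard_params([1e-300])
        s = draw_subjects(p, SimulationConfig(), rng, 1)[0]
        t, code = sample_event_time(p, s, SimulationConfig(), rng)
        assert (t, code) == (20.0, 0)

    def test_inversion_accuracy_against_closed_form(self, rng):
        # Weibull shape 2: T = scale * sqrt(-log(1-U))
        p = toy_params([CauseSpec(1, 2.0, 3.0)],
                       re_covariance=np.zeros((4, 4)))
        cfg = SimulationConfig(censor_time=1e6)
        subs = draw_subjects(p, cfg, rng, 200)
        r2 = np.random.default_rng(123)
        u = r2.uniform(size=200)
        hb = hazard_batch(p, np.zeros((200, 4)), np.zeros((200, 0)))
        from jmsched._quad import QuadratureRule
        T = _engine.invert_total_cumhaz(hb, -np.log1p(-u), 100.0,
                                        QuadratureRule())
        np.testing.assert_allclose(T, 3.0 * np.sqrt(-np.log1p(-u)), atol=2e-6)


class TestObserveBiomarkers:
    def test_zero_noise_recovers_linear_predictor(self, published_params, rng):
        p = replace(published_params, longitudinal=tuple(
            replace(sp, residual_sd=1e-12)
            for sp in published_params.longitudinal))
        s = SubjectTruth("s", np.array([0.1, 0.01, -0.2, 0.02]),
                         np.array([20.0]))
        df = observe_biomarkers(p, s, [0.0, 1.0], SimulationConfig(), rng)
        tn = df[df.outcome == "log_troponin"].sort_values("time_years")
        np.testing.assert_allclose(
            tn.value.to_numpy(), [2.8788 + 0.1, 2.8788 + 0.1 + 0.0537 + 0.01],
            atol=1e-6)

    def test_misspecified_residual_moments_and_skewness(self, published_params):
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(scenario="misspecified")
        s = SubjectTruth("s", np.zeros(4), np.array([22.0]))
        n = 20_000
        sigma = published_params.longitudinal[1].residual_sd
        df = observe_biomarkers(published_params, s,
                                np.linspace(0, 1, n), cfg, rng)
        nt = df[df.outcome == "log_ntprobnp"]
        eta = 4.6624 + 0.0472 * nt.time_years.to_numpy()
        resid = nt.value.to_numpy() - eta
        assert abs(resid.mean()) < 3 * sigma / np.sqrt(n)
        assert abs(resid.std() - sigma) < 0.05 * sigma
        skew = np.mean((resid / resid.std()) ** 3)
        assert abs(skew - 2.0) < 0.2  # Exp(1) skewness
        # troponin residuals stay Gaussian (symmetric)
        tn = df[df.outcome == "log_troponin"]
        rtn = tn.value.to_numpy() - (2.8788 + 0.0537 * tn.time_years.to_numpy())
        assert abs(np.mean((rtn / rtn.std()) ** 3)) < 0.2

    def test_visits_after_event_dropped_with_warning(self, published_params,
                                                     rng, caplog):
        s = SubjectTruth("s", np.zeros(4), np.array([22.0]),
                         true_event_time=1.0, true_cause=1)
        import logging
        with caplog.at_level(logging.WARNING, logger="jmsched.simulator"):
            df = observe_biomarkers(published_params, s, [0.0, 0.5, 1.5],
                                    SimulationConfig(), rng)
        assert set(df.time_years) == {0.0, 0.5}
        assert "dropping" in caplog.text


class TestGenerateDataset:
    def test_deterministic_given_seed(self, published_params):
        cfg = SimulationConfig(n_train=4, n_test=2)
        d1 = generate_dataset(published_params, cfg, np.random.default_rng(5))
        d2 = generate_dataset(published_params, cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(d1.train_longitudinal,
                                      d2.train_longitudinal)
        pd.testing.assert_frame_equal(d1.train_survival, d2.train_survival)
        assert d1.train_longitudinal.to_csv() == d2.train_longitudinal.to_csv()

    def test_short_censoring_leaves_no_events(self, published_params):
        cfg = SimulationConfig(n_train=30, n_test=2, censor_time=0.25)
        ds = generate_dataset(published_params, cfg, np.random.default_rng(1))
        assert (ds.train_survival.event_code == 0).all()
        assert (ds.train_longitudinal.time_years < 0.25).all()

    def test_training_visits_quarterly_until_event(self, published_params):
        cfg = SimulationConfig(n_train=10, n_test=2)
        ds = generate_dataset(published_params, cfg, np.random.default_rng(2))
        for sid, g in ds.train_longitudinal.groupby("subject_id"):
            times = np.sort(g[g.outcome == "log_troponin"].time_years.unique())
            np.testing.assert_allclose(np.diff(times), 0.25, atol=1e-12)
            T = ds.train_survival.set_index("subject_id").loc[sid, "time_years"]
            assert times.max() < T

    def test_warmup_records_only_for_test_arm(self, published_params):
        cfg = SimulationConfig(n_train=5, n_test=4)
        ds = generate_dataset(published_params, cfg, np.random.default_rng(3))
        assert set(ds.test_warmup_longitudinal.time_years) <= {0.0, 0.25, 0.5}
        assert len(ds.test_truths) == 4


class TestCalibration:
    def test_single_cause_closed_form(self, rng):
        # constant hazard, no covariates, no heterogeneity: fraction by T is
        # 1 - exp(-T/scale)
        p = constant_hazard_params([1.0], re_covariance=np.zeros((4, 4)))
        cfg = SimulationConfig(calibration_horizon=5.0, calibration_n=4000)
        target = 0.30
        cal, info = calibrate_weibull(p, [target], cfg, rng)
        expected_scale = -5.0 / np.log(1 - target)
        assert cal.causes[0].weibull_scale == pytest.approx(expected_scale,
                                                            rel=0.05)

    def test_self_consistency_with_exact_sampler(self, published_params):
        cfg = SimulationConfig(calibration_n=8000)
        targets = (90 / 381, 14 / 381)
        cal, info = calibrate_weibull(published_params, targets, cfg,
                                      np.random.default_rng(0))
        assert np.max(np.abs(info["achieved_fractions"] - targets)) < 0.01
        r2 = np.random.default_rng(99)
        subs = draw_subjects(cal, cfg, r2, 6000)
        sample_event_times(cal, subs, cfg, r2)
        T = np.array([s.true_event_time for s in subs])
        C = np.array([s.true_cause for s in subs])
        for k, tgt in zip((1, 2), targets):
            frac = np.mean((C == k) & (T <= cfg.calibration_horizon))
            assert abs(frac - tgt) < 0.015

    def test_swapped_targets_swap_hazard_ordering(self, published_params):
        cfg = SimulationConfig(calibration_n=3000)
        cal_a, _ = calibrate_weibull(published_params, (0.2, 0.05), cfg,
                                     np.random.default_rng(1))
        cal_b, _ = calibrate_weibull(published_params, (0.05, 0.2), cfg,
                                     np.random.default_rng(1))
        # a larger target fraction needs a larger hazard, i.e. smaller scale
        assert cal_a.causes[0].weibull_scale < cal_a.causes[1].weibull_scale \
            or cal_b.causes[0].weibull_scale > cal_b.causes[1].weibull_scale

    def test_unreachable_targets_raise(self, published_params):
        cfg = SimulationConfig(calibration_n=500)
        with pytest.raises((CalibrationError, ValueError)):
            calibrate_weibull(published_params, (0.7, 0.5), cfg,
                              np.random.default_rng(2))


class TestDistributionalAgreement:
    def test_empirical_survival_within_dkw_band(self, published_params):
        # one fixed subject, many replicate event times
        rng = np.random.default_rng(17)
        b = np.array([0.2, 0.01, -0.3, 0.02])
        cfg = SimulationConfig(censor_time=1e6)
        n = 10_000
        subs = [SubjectTruth(f"r{i}", b, np.array([22.0])) for i in range(n)]
        sample_event_times(published_params, subs, cfg, rng)
        T = np.sort([s.true_event_time for s in subs])
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))  # 99% DKW band
        for t in (0.5, 2.0, 5.0, 10.0, 19.0):
            S_emp = np.mean(T > t)
            S_true = overall_survival(published_params,
                                      subs[0], t)
            assert abs(S_emp - S_true) < eps

    def test_simulated_cause_incidence_matches_cif(self, published_params):
        # cohort-level: empirical cause-1 incidence vs subject-averaged CIF
        rng = np.random.default_rng(23)
        cfg = SimulationConfig()
        n = 5000
        subs = draw_subjects(published_params, cfg, rng, n)
        hb = hazard_batch(published_params,
                          np.stack([s.random_effects for s in subs]),
                          np.stack([s.baseline_covariates for s in subs]))
        sample_event_times(published_params, subs, cfg, rng)
        T = np.array([s.true_event_time for s in subs])
        C = np.array([s.true_cause for s in subs])
        for t_chk in (2.0, 5.0, 10.0):
            grid = np.linspace(t_chk / 8, t_chk, 8)
            pi, _ = _engine.conditional_cif_curve(hb, 0, 0.0, grid, 8)
            expected = pi[:, -1].mean()
            observed = np.mean((C == 1) & (T <= t_chk))
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 4 * se
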