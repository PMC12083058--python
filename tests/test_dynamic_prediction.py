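"""The Monte-Carlo risk estimator against conjugate, degenerate and
closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from helpers import constant_hazard_params, toy_params, value_assoc_cause
from jmsched import (McConfig, PatientHistory, SimulationConfig, SubjectTruth,
                     degenerate_posterior, observe_biomarkers, predict_cif,
                     predict_cif_curve, sample_conditional_random_effects,
                     true_conditional_cif)
from jmsched.simulator import draw_subjects, sample_event_times


def make_history(records=None, t=0.0, maggic=()):
    df = pd.DataFrame(records or [],
                      columns=["subject_id", "outcome", "time_years", "value"])
    return PatientHistory("pt", df, np.asarray(maggic, dtype=float), t)


def gaussian_conditional_oracle(params, records_df, t):
    """Closed-form p(b | longitudinal records) for the conjugate check,
    assembled directly from the normal-equations algebra."""
    D = params.re_covariance
    prec = np.linalg.inv(D)
    qv = np.zeros(4)
    for p_i, sp in enumerate(params.longitudinal):
        g = records_df[records_df.outcome == sp.outcome_name]
        if not len(g):
            continue
        tt = g.time_years.to_numpy()
        y = g.value.to_numpy()
        X = np.column_stack([np.ones_like(tt), tt])
        r = y - X @ np.asarray(sp.fixed_effects)
        sl = slice(2 * p_i, 2 * p_i + 2)
        prec[sl, sl] += X.T @ X / sp.residual_sd**2
        qv[sl] += X.T @ r / sp.residual_sd**2
    cov = np.linalg.inv(prec)
    return cov @ qv, cov


class TestConditionalRandomEffects:
    def test_zero_association_recovers_conjugate_gaussian(self, published_params):
        # alpha = 0: the survival factor is flat, so the sampler's stationary
        # law is exactly the closed-form Gaussian longitudinal conditional
        p = toy_params([value_assoc_cause(1, 1.0, 50.0)],
                       re_covariance=published_params.re_covariance)
        recs = [("pt", "log_troponin", 0.0, 3.1), ("pt", "log_troponin", 0.5, 3.2),
                ("pt", "log_ntprobnp", 0.0, 5.0), ("pt", "log_ntprobnp", 0.5, 5.4)]
        hist = make_history(recs, t=1.0)
        rng = np.random.default_rng(3)
        draws, acc = sample_conditional_random_effects(p, hist, rng, 5000)
        assert acc == 1.0
        mean_o, cov_o = gaussian_conditional_oracle(p, hist.records, 1.0)
        se = np.sqrt(np.diag(cov_o) / 5000)
        assert np.all(np.abs(draws.mean(axis=0) - mean_o) < 3 * se)
        assert np.linalg.norm(np.cov(draws.T) - cov_o) \
            < 0.1 * np.linalg.norm(cov_o)

    def test_prior_recovery_without_data(self, published_params):
        p = toy_params([value_assoc_cause(1, 1.0, 50.0)],
                       re_covariance=published_params.re_covariance)
        hist = make_history(t=0.0)
        draws, _ = sample_conditional_random_effects(
            p, hist, np.random.default_rng(4), 5000)
        D = published_params.re_covariance
        se = np.sqrt(np.diag(D) / 5000)
        assert np.all(np.abs(draws.mean(axis=0)) < 3.5 * se)
        assert np.linalg.norm(np.cov(draws.T) - D) < 0.1 * np.linalg.norm(D)

    def test_survival_conditioning_shifts_effects_down(self, published_params):
        # strong positive association + long event-free survival makes large
        # random effects unlikely; oracle direction via importance weighting
        p = toy_params([value_assoc_cause(1, 1.0, 5600.0, alpha_tn=1.0,
                                          alpha_nt=1.0)],
                       re_covariance=published_params.re_covariance)
        t_surv = 3.0
        hist = make_history(t=t_surv)
        rng = np.random.default_rng(5)
        draws, acc = sample_conditional_random_effects(p, hist, rng, 4000,
                                                       McConfig(mh_steps=80))
        assert 0 < acc <= 1
        # importance-sampling oracle on prior draws
        r2 = np.random.default_rng(6)
        from jmsched.model_core import hazard_batch
        from jmsched import _engine
        from jmsched._quad import panel_boundaries
        bprior = r2.multivariate_normal(np.zeros(4), p.re_covariance, 20_000)
        hb = hazard_batch(p, bprior, np.zeros((20_000, 0)))
        H = _engine.cumhaz_at_boundaries(
            hb, panel_boundaries(0, t_surv, 0.5), 10).sum(axis=0)[:, -1]
        wts = np.exp(-H); wts /= wts.sum()
        combo = bprior[:, 0] + bprior[:, 2]  # intercepts drive the hazard
        oracle_shift = wts @ combo
        mh_shift = (draws[:, 0] + draws[:, 2]).mean()
        assert oracle_shift < -0.05          # conditioning really binds
        assert mh_shift < 0.0                # sampler shifts the same way
        assert abs(mh_shift - oracle_shift) < 0.15

    def test_zero_acceptance_raises(self, published_params):
        from jmsched.dynamic_prediction import ZeroAcceptanceError
        # astronomically strong association: every proposal is rejected
        # against an initial state that got lucky, or S(t) underflows
        p = toy_params([value_assoc_cause(1, 1.0, 1e-4, alpha_tn=30.0)],
                       re_covariance=published_params.re_covariance)
        hist = make_history(t=10.0)
        with pytest.raises((ZeroAcceptanceError, FloatingPointError)):
            sample_conditional_random_effects(
                p, hist, np.random.default_rng(7), 200)


class TestPredictCif:
    def test_vanishing_window_risk(self):
        p = constant_hazard_params([0.2], re_covariance=np.zeros((4, 4)))
        post = degenerate_posterior(p)
        pred = predict_cif(post, make_history(t=1.0), 1, 1.0 + 1e-7,
                           np.random.default_rng(0))
        assert pred.point_estimate < 1e-6

    def test_degenerate_posterior_equals_true_cif(self, published_params):
        # D -> 0 and sigma known: b is pinned at zero, the prediction is a
        # deterministic quadrature and must match the true conditional CIF
        p = replace(published_params, re_covariance=np.zeros((4, 4)))
        post = degenerate_posterior(p)
        hist = make_history(t=1.5, maggic=[22.0])
        s = SubjectTruth("pt", np.zeros(4), np.array([22.0]))
        for horizon in (2.0, 4.0):
            pred = predict_cif(post, hist, 1, horizon,
                               np.random.default_rng(0),
                               McConfig(n_theta=1, n_b=1, mh_steps=5))
            truth = true_conditional_cif(p, s, 1, 1.5, horizon)
            assert pred.point_estimate == pytest.approx(truth, rel=2e-3)

    def test_constant_hazard_closed_form(self):
        lam = 0.3
        p = constant_hazard_params([lam], re_covariance=np.zeros((4, 4)))
        post = degenerate_posterior(p)
        pred = predict_cif(post, make_history(t=2.0), 1, 3.5,
                           np.random.default_rng(1),
                           McConfig(n_theta=1, n_b=1))
        assert pred.point_estimate == pytest.approx(1 - np.exp(-lam * 1.5),
                                                    rel=1e-6)

    def test_competing_risk_split(self):
        p = constant_hazard_params([0.3, 0.1], re_covariance=np.zeros((4, 4)))
        post = degenerate_posterior(p)
        pred = predict_cif(post, make_history(t=0.0), 2, 2.0,
                           np.random.default_rng(1), McConfig(n_theta=1, n_b=1))
        expected = 0.25 * (1 - np.exp(-0.4 * 2.0))
        assert pred.point_estimate == pytest.approx(expected, rel=1e-6)


class TestCifCurve:
    def test_matches_separate_calls_with_same_seed(self, published_params):
        post = degenerate_posterior(published_params, n_draws=3)
        hist = make_history([("pt", "log_troponin", 0.0, 3.0),
                             ("pt", "log_ntprobnp", 0.0, 5.0)],
                            t=0.5, maggic=[22.0])
        mc = McConfig(n_theta=3, n_b=2, mh_steps=10)
        curve = predict_cif_curve(post, hist, 1, np.array([1.0, 1.5]),
                                  np.random.default_rng(42), mc)
        single = predict_cif(post, hist, 1, 1.0, np.random.default_rng(42), mc)
        np.testing.assert_allclose(curve[0].draws, single.draws, rtol=1e-12)

    def test_per_draw_monotonicity(self, published_params):
        post = degenerate_posterior(published_params, n_draws=5)
        hist = make_history([("pt", "log_troponin", 0.0, 3.4),
                             ("pt", "log_ntprobnp", 0.0, 5.6)],
                            t=0.5, maggic=[25.0])
        s_grid = 0.5 + np.linspace(0.05, 3.0, 20)
        curve = predict_cif_curve(post, hist, 1, s_grid,
                                  np.random.default_rng(2),
                                  McConfig(n_theta=5, n_b=4, mh_steps=10))
        assert np.all(np.diff(curve.pi_draws, axis=1) >= -1e-15)
        points = [curve[i].point_estimate for i in range(len(curve))]
        assert np.all(np.diff(points) >= -1e-15)
        # interval envelope is ordered
        for i in range(len(curve)):
            rp = curve[i]
            assert rp.lower95 <= rp.point_estimate <= rp.upper95
            assert np.all((rp.draws >= 0) & (rp.draws <= 1))

    def test_single_cause_saturates_to_one(self):
        p = constant_hazard_params([0.5], re_covariance=np.zeros((4, 4)))
        post = degenerate_posterior(p)
        curve = predict_cif_curve(post, make_history(t=0.0), 1,
                                  np.array([10.0, 40.0]),
                                  np.random.default_rng(0),
                                  McConfig(n_theta=1, n_b=1, quad_width=1.0))
        assert curve[1].point_estimate > 0.999

    def test_mc_error_shrinks_with_draws(self, published_params):
        hist = make_history([("pt", "log_troponin", 0.0, 3.2),
                             ("pt", "log_ntprobnp", 0.0, 5.2)],
                            t=0.0, maggic=[22.0])
        post = degenerate_posterior(published_params, n_draws=1)
        sds = []
        for n_b in (8, 32, 128):
            ests = []
            for rep in range(12):
                pred = predict_cif(post, hist, 1, 1.0,
                                   np.random.default_rng(1000 + rep),
                                   McConfig(n_theta=1, n_b=n_b, mh_steps=0))
                ests.append(pred.point_estimate)
            sds.append(np.std(ests))
        # quadrupling draws should halve the SE, within stochastic slack
        assert sds[2] < sds[1] < sds[0]
        assert sds[0] / sds[2] > 2.0


class TestSelfConsistencyCalibration:
    def test_predicted_deciles_match_observed_incidence(self, published_params):
        """Simulate from theta0, predict under the degenerate posterior
        {theta0} given each subject's baseline measurements, and check
        group-level calibration of the 1-year cause-1 risk."""
        rng = np.random.default_rng(31)
        cfg = SimulationConfig()
        n = 800
        subs = draw_subjects(published_params, cfg, rng, n)
        post = degenerate_posterior(published_params)
        mc = McConfig(n_theta=1, n_b=60, mh_steps=0)
        preds = np.empty(n)
        for i, s in enumerate(subs):
            obs = observe_biomarkers(published_params, s, [0.0], cfg, rng)
            hist = PatientHistory(s.subject_id, obs, s.baseline_covariates, 0.0)
            preds[i] = predict_cif(post, hist, 1, 1.0,
                                   np.random.default_rng(50_000 + i), mc
                                   ).point_estimate
        sample_event_times(published_params, subs, cfg, rng)
        events = np.array([s.true_cause == 1 and s.true_event_time <= 1.0
                           for s in subs])
        qs = np.quantile(preds, [0.0, 0.25, 0.5, 0.75, 1.0])
        for lo, hi in zip(qs[:-1], qs[1:]):
            grp = (preds >= lo) & (preds <= hi)
            ng = grp.sum()
            if ng < 50:
                continue
            p_hat = preds[grp].mean()
            obs_rate = events[grp].mean()
            bound = 1.96 * np.sqrt(max(p_hat * (1 - p_hat), 1e-4) / ng) + 0.01
            assert abs(obs_rate - p_hat) < bound, (lo, hi, p_hat, obs_rate)
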