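"""Visit-scheduling strategies: fixed intervals and risk-based rules.

At each decision visit at time t the Delta-horizon risk pi_k(t, t+Delta) is
estimated; if the point estimate reaches the interruption threshold kappa,
monitoring stops for therapy adjustment.  Otherwise the next visit is placed
at t + u where

* fixed strategies use a constant u,
* the regular risk-based rule solves  pi_hat(t, t+u) = lambda  on (0, u_max]
  (cumulative risk until the next visit is capped at lambda),
* the conservative variant solves the same equation for the upper 97.5%
  posterior quantile of the risk, yielding intervals never longer than the
  regular rule's for the same prediction draws,
* the multi-endpoint rule takes the minimum of per-cause regular intervals.

All strategies share a warm-up protocol (quarterly visits for the first half
year, no risk predictions) and the same interrupt test; the interrupt test
and the interval rule at a visit use one shared prediction object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulator
from .dynamic_prediction import (CifCurve, McConfig, PatientHistory,
                                 RiskPrediction, predict_cif_curve)
from .inference import PosteriorDraws
from .model_core import JointModelParams, SubjectTruth

logger = logging.getLogger(__name__)

STRATEGY_KINDS = ("fixed", "risk_based", "risk_based_conservative",
                  "risk_based_multi")

#: smallest admissible inter-visit gap (years); prevents degenerate zero-gap
#: loops when the predicted risk sits between lambda and kappa at tiny u
MIN_INTERVAL = 0.05

_BISECT_TOL = 1e-3  # years


@dataclass
class StrategyConfig:
    """One scheduling strategy."""

    kind: str = "risk_based"
    name: str | None = None
    fixed_interval: float = 0.25
    lambda_: float | tuple[float, ...] = 0.01
    kappa: float = 0.10
    delta: float = 1.0
    u_max: float | tuple[float, ...] = 1.0
    warmup_visits: tuple[float, ...] = (0.0, 0.25, 0.5)
    interrupt_cause: int = 1
    min_interval: float = MIN_INTERVAL

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"kind must be one of {STRATEGY_KINDS}")
        lam = np.atleast_1d(np.asarray(self.lambda_, dtype=float))
        if np.any(lam <= 0) or np.any(lam > self.kappa) or self.kappa >= 1:
            raise ValueError("need 0 < lambda <= kappa < 1")
        if self.delta <= 0 or np.any(np.atleast_1d(self.u_max) <= 0):
            raise ValueError("delta and u_max must be > 0")
        w = np.asarray(self.warmup_visits, dtype=float)
        if len(w) == 0 or w[0] != 0 or np.any(np.diff(w) <= 0):
            raise ValueError("warmup_visits must increase from 0")
        if self.kind == "fixed" and self.fixed_interval <= 0:
            raise ValueError("fixed_interval must be > 0")
        if self.name is None:
            self.name = (f"fixed_{self.fixed_interval:g}" if self.kind == "fixed"
                         else self.kind)

    @property
    def warmup_end(self) -> float:
        return float(self.warmup_visits[-1])


@dataclass
class ScheduleTrace:
    """Realized monitoring history of one test patient under one strategy."""

    subject_id: str
    strategy: str
    visit_times: list[float]
    predictions: list[RiskPrediction]   # one per decision visit, window (t, t+Delta)
    interrupted: bool
    interruption_time: float | None
    termination: str                    # interrupted | event | censored
    event_code_at_termination: int
    floor_hits: int = 0                 # times the minimum-interval floor bound

    def __post_init__(self) -> None:
        v = np.asarray(self.visit_times, dtype=float)
        if len(v) > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("visit_times must be strictly increasing")
        if self.interrupted and self.interruption_time not in self.visit_times:
            raise ValueError("interruption_time must be a visit time")


# ---------------------------------------------------------------------------
# interval rules
# ---------------------------------------------------------------------------

def _solve_interval(value_at, t: float, lambda_: float, u_max: float,
                    min_interval: float = MIN_INTERVAL) -> tuple[float, bool]:
    """Smallest-risk-crossing interval: the u in (0, u_max] with
    value_at(t+u) = lambda, by bisection on a monotone curve.

    Returns (u, floor_bound).  Caps at u_max when even the full interval
    stays below lambda; floors at min_interval when the risk already exceeds
    lambda there.
    """
    if value_at(t + u_max) < lambda_:
        return u_max, False
    if value_at(t + min_interval) >= lambda_:
        logger.debug("minimum-interval floor binding at t=%.3f", t)
        return min_interval, True
    lo, hi = min_interval, u_max
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if value_at(t + mid) < lambda_:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def next_interval_risk_based(predict_curve, t: float, lambda_: float,
                             u_max: float,
                             min_interval: float = MIN_INTERVAL
                             ) -> tuple[float, bool]:
    """Regular rule: pi_hat point estimate caps the inter-visit risk at
    lambda.  ``predict_curve`` must expose ``mean_at(s)`` monotone in s."""
    if not 0 < lambda_ < 1:
        raise ValueError("lambda must be in (0, 1)")
    if u_max <= 0:
        raise ValueError("u_max must be > 0")
    return _solve_interval(predict_curve.mean_at, t, lambda_, u_max,
                           min_interval)


def next_interval_conservative(predict_curve, t: float, lambda_: float,
                               u_max: float,
                               min_interval: float = MIN_INTERVAL
                               ) -> tuple[float, bool]:
    """Conservative rule: the upper 97.5% posterior quantile of the risk
    caps the inter-visit risk; never exceeds the regular rule's interval for
    the same draws."""
    if not 0 < lambda_ < 1:
        raise ValueError("lambda must be in (0, 1)")
    return _solve_interval(predict_curve.upper_at, t, lambda_, u_max,
                           min_interval)


def next_interval_multi(predict_curves, t: float, lambdas, u_maxes,
                        min_interval: float = MIN_INTERVAL
                        ) -> tuple[float, bool]:
    """Multi-endpoint rule: minimum of per-cause regular intervals."""
    curves = list(predict_curves)
    lambdas = np.broadcast_to(np.atleast_1d(lambdas), (len(curves),))
    u_maxes = np.broadcast_to(np.atleast_1d(u_maxes), (len(curves),))
    best, floored = np.inf, False
    for curve, lam, um in zip(curves, lambdas, u_maxes):
        u, fl = next_interval_risk_based(curve, t, float(lam), float(um),
                                         min_interval)
        if u < best:
            best, floored = u, fl
    return float(best), floored


# ---------------------------------------------------------------------------
# full per-patient protocol
# ---------------------------------------------------------------------------

def run_strategy(subject: SubjectTruth, params_for_observation: JointModelParams,
                 posterior: PosteriorDraws, strategy: StrategyConfig,
                 sim_config: simulator.SimulationConfig,
                 rng: np.random.Generator,
                 mc_config: McConfig | None = None,
                 warmup_records: pd.DataFrame | None = None) -> ScheduleTrace:
    """Simulate one patient's monitoring under a strategy.

    Observations are generated from the subject's latent truth via the
    simulator; risk predictions use the fitted posterior.  Monitoring stops
    when the Delta-horizon risk point estimate reaches kappa (interruption),
    or when the subject's event/censoring time arrives before the next
    visit.  The last warm-up visit doubles as the first decision visit.
    """
    if subject.true_event_time is None:
        raise ValueError("subject needs a sampled event time")
    mc = mc_config or McConfig()
    t_end = float(subject.true_event_time)
    warm = [t for t in strategy.warmup_visits if t < t_end]

    if warmup_records is None:
        records = simulator.observe_biomarkers(
            params_for_observation, subject, warm, sim_config, rng)
    else:
        records = warmup_records[warmup_records["time_years"] < t_end].copy()
    visits = list(warm)
    predictions: list[RiskPrediction] = []
    floor_hits = 0

    def terminal(code: int) -> str:
        return "censored" if code == 0 else "event"

    if len(warm) < len(strategy.warmup_visits):
        # endpoint during warm-up: no decisions were ever made
        return ScheduleTrace(subject.subject_id, strategy.name, visits, [],
                             False, None, terminal(subject.true_cause),
                             subject.true_cause)

    causes = ([strategy.interrupt_cause] if strategy.kind != "risk_based_multi"
              else [cs.cause_code for cs in posterior.draws[0].causes])
    horizon = max(strategy.delta, float(np.max(strategy.u_max)))
    s_points = max(8, int(np.ceil(horizon / 0.125)))
    t = strategy.warmup_end
    while True:
        history = PatientHistory(subject_id=subject.subject_id,
                                 records=records,
                                 baseline_covariates=subject.baseline_covariates,
                                 t=t)
        s_grid = t + np.linspace(horizon / s_points, horizon, s_points)
        curves: dict[int, CifCurve] = {
            k: predict_cif_curve(posterior, history, k, s_grid, rng, mc)
            for k in causes}
        main = curves[strategy.interrupt_cause] if strategy.kind != "risk_based_multi" \
            else curves[causes[0]]
        # single shared prediction object: the kappa-test and the interval
        # rule both read this curve
        pred = main.prediction_at(t + strategy.delta)
        predictions.append(pred)
        if pred.point_estimate >= strategy.kappa:
            return ScheduleTrace(subject.subject_id, strategy.name, visits,
                                 predictions, True, t, "interrupted",
                                 subject.true_cause, floor_hits)
        if strategy.kind == "fixed":
            u, fl = strategy.fixed_interval, False
        elif strategy.kind == "risk_based":
            u, fl = next_interval_risk_based(
                main, t, float(np.atleast_1d(strategy.lambda_)[0]),
                float(np.atleast_1d(strategy.u_max)[0]), strategy.min_interval)
        elif strategy.kind == "risk_based_conservative":
            u, fl = next_interval_conservative(
                main, t, float(np.atleast_1d(strategy.lambda_)[0]),
                float(np.atleast_1d(strategy.u_max)[0]), strategy.min_interval)
        else:  # risk_based_multi
            u, fl = next_interval_multi(
                [curves[k] for k in causes], t, strategy.lambda_,
                strategy.u_max, strategy.min_interval)
        floor_hits += int(fl)
        t_next = t + max(u, strategy.min_interval)
        if t_next >= t_end:
            return ScheduleTrace(subject.subject_id, strategy.name, visits,
                                 predictions, False, None,
                                 terminal(subject.true_cause),
                                 subject.true_cause, floor_hits)
        new_obs = simulator.observe_biomarkers(params_for_observation, subject,
                                               [t_next], sim_config, rng)
        records = pd.concat([records, new_obs], ignore_index=True)
        visits.append(t_next)
        t = t_next
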