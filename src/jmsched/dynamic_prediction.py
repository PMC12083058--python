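"""Monte-Carlo dynamic prediction of conditional cumulative incidence.

For a new patient with biomarker history to time t and no event by t, the
Delta-horizon risk of cause k,

    pi_k(t, s) = Pr(T*_k < s | T* > t, history, training data),

is estimated by the posterior-predictive Monte Carlo scheme: for each
retained posterior draw of theta, draw random effects b from

    p(b | history, T* > t; theta)  ∝  N(b; 0, D)
                                      x prod_j N(y_j; eta(t_j; b), sigma^2)
                                      x S(t | b)

and average the conditional cumulative incidence CIF_k(t, s | b) / S(t | b)
over the (theta, b) draws.  The b-sampler is an independence
Metropolis-Hastings chain whose proposal is the exact Gaussian conditional
given the longitudinal data alone (conjugate), so the acceptance ratio
reduces to S(t | b') / S(t | b); when the association is zero the proposal
is the target and every step is accepted.

Curves over a horizon grid share their (theta, b) draws across grid points,
which makes every per-draw curve (and hence the point estimate) exactly
nondecreasing in s -- the property the scheduler's root-finder relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from ._quad import panel_boundaries
from .inference import PosteriorDraws
from .model_core import JointModelParams

DEFAULT_S_POINTS = 16


@dataclass
class McConfig:
    """Monte-Carlo budgets for one prediction call."""

    n_theta: int = 200      # posterior draws used
    n_b: int = 5            # random-effects draws per theta draw
    mh_steps: int = 50      # independence-MH steps per b chain
    quad_width: float = 0.25   # panel width for survival-to-t quadrature
    quad_nodes: int = 7        # nodes for cumulative-hazard and CIF panels
    cif_nodes: int = 8         # outer/inner nodes of the nested CIF rule


@dataclass
class PatientHistory:
    """Longitudinal records up to the prediction time t plus baseline
    covariates."""

    subject_id: str
    records: pd.DataFrame          # columns: subject_id, outcome, time_years, value
    baseline_covariates: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.baseline_covariates = np.atleast_1d(
            np.asarray(self.baseline_covariates, dtype=float))
        if self.t < 0:
            raise ValueError("history time t must be >= 0")
        if len(self.records) and (self.records["time_years"] > self.t + 1e-9).any():
            raise ValueError("history contains records after time t")


@dataclass
class RiskPrediction:
    """Monte-Carlo draws of pi_k(t, s) with point estimate and 95% interval."""

    cause: int
    window: tuple[float, float]
    draws: np.ndarray
    point_estimate: float = field(init=False)
    lower95: float = field(init=False)
    upper95: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float).ravel()
        self.draws = d
        self.point_estimate = float(np.mean(d))
        self.lower95 = float(np.quantile(d, 0.025))
        self.upper95 = float(np.quantile(d, 0.975))


class ZeroAcceptanceError(RuntimeError):
    """The b-sampler accepted no proposal in an entire batch."""


# ---------------------------------------------------------------------------
# batched posterior arrays
# ---------------------------------------------------------------------------

def _posterior_arrays(posterior: PosteriorDraws, n_theta: int) -> dict:
    """Stack the per-draw parameters needed for prediction into arrays;
    cached on the posterior object."""
    key = ("arrays", n_theta)
    if key in posterior._batch_cache:
        return posterior._batch_cache[key]
    m = len(posterior.draws)
    take = np.linspace(0, m - 1, min(n_theta, m)).astype(int)
    draws = [posterior.draws[i] for i in take]
    M = len(draws)
    p0 = draws[0]
    P = len(p0.longitudinal)
    K = p0.n_causes
    q = p0.n_random_effects
    W = len(p0.baseline_covariate_names)
    arr = {
        "M": M, "P": P, "K": K, "q": q, "W": W,
        "outcome_names": tuple(sp.outcome_name for sp in p0.longitudinal),
        "cause_codes": tuple(cs.cause_code for cs in p0.causes),
        "beta": np.zeros((M, P, 2)),
        "sigma": np.zeros((M, P)),
        "D": np.zeros((M, q, q)),
        "shapes": np.zeros((K, M)),
        "scales": np.zeros((K, M)),
        "gamma": np.zeros((K, M, W)),
        "alpha": np.zeros((K, M, P)),
    }
    for j, prm in enumerate(draws):
        for p, sp in enumerate(prm.longitudinal):
            fe = np.zeros(2)
            fe[:len(sp.fixed_effects)] = sp.fixed_effects[:2]
            arr["beta"][j, p] = fe
            arr["sigma"][j, p] = sp.residual_sd
        arr["D"][j] = prm.re_covariance
        for k, cs in enumerate(prm.causes):
            arr["shapes"][k, j] = cs.weibull_shape
            arr["scales"][k, j] = cs.weibull_scale
            arr["gamma"][k, j] = cs.baseline_coefficients
            amap = {t.outcome_name: float(t.coefficient)
                    for t in cs.association_terms}
            for p, nm in enumerate(arr["outcome_names"]):
                arr["alpha"][k, j, p] = amap.get(nm, 0.0)
    posterior._batch_cache[key] = arr
    return arr


def _hazard_batch_draws(arr: dict, b: np.ndarray, w: np.ndarray) -> _engine.HazardBatch:
    """HazardBatch over flattened (theta, b) pairs.

    b: (M, nb, q); w: (W,).  Exponent polynomial per cause:
    gamma'w + sum_p alpha_p * [(beta_p0 + b_p0) + (beta_p1 + b_p1) t].
    """
    M, nb = b.shape[0], b.shape[1]
    K, P = arr["K"], arr["P"]
    expo = np.zeros((K, M, nb, 2))
    for k in range(K):
        gw = arr["gamma"][k] @ w  # (M,)
        c0 = gw[:, None] + np.zeros((M, nb))
        c1 = np.zeros((M, nb))
        for p in range(P):
            a = arr["alpha"][k, :, p][:, None]  # (M,1)
            c0 = c0 + a * (arr["beta"][:, p, 0][:, None] + b[:, :, 2 * p])
            c1 = c1 + a * (arr["beta"][:, p, 1][:, None] + b[:, :, 2 * p + 1])
        expo[k, :, :, 0] = c0
        expo[k, :, :, 1] = c1
    N = M * nb
    shapes = np.repeat(arr["shapes"], nb, axis=1)
    scales = np.repeat(arr["scales"], nb, axis=1)
    return _engine.HazardBatch(shapes=shapes, scales=scales,
                               expo=expo.reshape(K, N, 2))


# ---------------------------------------------------------------------------
# conditional random-effects sampler
# ---------------------------------------------------------------------------

def _history_stats(arr: dict, history: PatientHistory) -> tuple[np.ndarray, np.ndarray]:
    """Per-outcome sufficient statistics of the history: XtX (P,2,2),
    Xty (P,2), yty (P,), n (P,)."""
    P = arr["P"]
    XtX = np.zeros((P, 2, 2))
    Xty = np.zeros((P, 2))
    for p, nm in enumerate(arr["outcome_names"]):
        g = history.records[history.records["outcome"] == nm]
        if len(g) == 0:
            continue
        t = g["time_years"].to_numpy(dtype=float)
        y = g["value"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(t), t])
        XtX[p] = X.T @ X
        Xty[p] = X.T @ y
    return XtX, Xty


def _gaussian_conditional(arr: dict, XtX: np.ndarray, Xty: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Mean (M,q) and Cholesky (M,q,q) of p(b | longitudinal history; theta)
    per theta draw (conjugate Gaussian)."""
    M, P, q = arr["M"], arr["P"], arr["q"]
    prec = np.linalg.inv(arr["D"] + 1e-12 * np.eye(q))
    qv = np.zeros((M, q))
    for p in range(P):
        inv_s2 = 1.0 / arr["sigma"][:, p] ** 2  # (M,)
        sl = slice(2 * p, 2 * p + 2)
        resid = Xty[p][None, :] - np.einsum("ij,mj->mi", XtX[p], arr["beta"][:, p])
        qv[:, sl] = resid * inv_s2[:, None]
        prec[:, sl, sl] += XtX[p][None] * inv_s2[:, None, None]
    cov = np.linalg.inv(prec)
    cov = (cov + np.swapaxes(cov, 1, 2)) / 2
    mean = np.einsum("mij,mj->mi", cov, qv)
    return mean, _chol_psd(cov)


def _chol_psd(cov: np.ndarray) -> np.ndarray:
    """Batched Cholesky with scale-aware jitter and an eigenvalue-clipping
    fallback for numerically indefinite matrices."""
    q = cov.shape[-1]
    scale = np.maximum(np.abs(cov).max(axis=(-2, -1), keepdims=True), 1e-30)
    try:
        return np.linalg.cholesky(cov + 1e-10 * scale * np.eye(q))
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, 1e-12 * scale[..., 0])
        fixed = np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)
        return np.linalg.cholesky(fixed + 1e-12 * scale * np.eye(q))


def _log_survival_t(arr: dict, b: np.ndarray, w: np.ndarray, t: float,
                    mc: McConfig) -> np.ndarray:
    """log S(t | b, theta) for b of shape (M, nb, q); returns (M, nb)."""
    M, nb = b.shape[0], b.shape[1]
    if t <= 0:
        return np.zeros((M, nb))
    hb = _hazard_batch_draws(arr, b, w)
    bounds = panel_boundaries(0.0, t, mc.quad_width)
    H = _engine.cumhaz_at_boundaries(hb, bounds, mc.quad_nodes).sum(axis=0)[:, -1]
    return -H.reshape(M, nb)


def sample_conditional_random_effects(theta_draw: JointModelParams,
                                      history: PatientHistory,
                                      rng: np.random.Generator,
                                      n_draws: int,
                                      mc_config: McConfig | None = None,
                                      ) -> tuple[np.ndarray, float]:
    """Draws from p(b | history, survival past t; theta) for one theta.

    Returns (draws (n_draws, q), acceptance_rate).  Exposed mainly for
    diagnostics and tests; predictions use the batched internal variant.
    """
    mc = mc_config or McConfig()
    post = PosteriorDraws(draws=[theta_draw], diagnostics={}, chains=1,
                          warmup=0, retained=1)
    arr = _posterior_arrays(post, 1)
    b, acc = _sample_b_batch(arr, history, rng, n_draws, mc)
    return b[0], acc


def _sample_b_batch(arr: dict, history: PatientHistory,
                    rng: np.random.Generator, n_b: int, mc: McConfig
                    ) -> tuple[np.ndarray, float]:
    """Independence-MH draws of b per theta draw; returns ((M, n_b, q), acc)."""
    M, q = arr["M"], arr["q"]
    XtX, Xty = _history_stats(arr, history)
    mean, chol = _gaussian_conditional(arr, XtX, Xty)
    w = history.baseline_covariates

    def propose(size):
        z = rng.standard_normal((M, size, q))
        return mean[:, None, :] + np.einsum("mij,msj->msi", chol, z)

    b = propose(n_b)
    assoc_active = np.any(arr["alpha"] != 0.0) and history.t > 0
    if not assoc_active:
        # survival factor constant in b: proposal == target
        return b, 1.0
    logS = _log_survival_t(arr, b, w, history.t, mc)
    if np.all(logS < -_engine._EXP_CLIP):
        raise FloatingPointError("S(t | b) underflows for every draw; "
                                 "conditioning on survival is undefined")
    accepted = 0
    total = 0
    for _ in range(mc.mh_steps):
        cand = propose(n_b)
        logS_cand = _log_survival_t(arr, cand, w, history.t, mc)
        logr = logS_cand - logS
        acc = np.log(rng.uniform(size=logr.shape)) < logr
        b = np.where(acc[..., None], cand, b)
        logS = np.where(acc, logS_cand, logS)
        accepted += int(acc.sum())
        total += acc.size
    rate = accepted / max(total, 1)
    if accepted == 0 and total >= 100:
        raise ZeroAcceptanceError(
            f"b-sampler accepted 0 of {total} proposals at t={history.t}")
    return b, rate


# ---------------------------------------------------------------------------
# CIF prediction
# ---------------------------------------------------------------------------

class CifCurve:
    """Shared-draw Monte-Carlo estimate of s -> pi_k(t, s).

    Sequence-like: ``curve[i]`` is the :class:`RiskPrediction` at
    ``s_grid[i]``.  ``mean_at`` / ``upper_at`` evaluate the point estimate
    and the 97.5% draw quantile at arbitrary s inside the grid range (used
    by the scheduler's bisection).
    """

    def __init__(self, cause: int, t: float, s_grid: np.ndarray,
                 pi_draws: np.ndarray, cache: dict, acceptance_rate: float):
        self.cause = cause
        self.t = float(t)
        self.s_grid = np.asarray(s_grid, dtype=float)
        self.pi_draws = pi_draws              # (n_draws, S), nondecreasing in s
        self._cache = cache
        self.acceptance_rate = acceptance_rate

    def __len__(self) -> int:
        return len(self.s_grid)

    def __getitem__(self, i: int) -> RiskPrediction:
        return RiskPrediction(cause=self.cause,
                              window=(self.t, float(self.s_grid[i])),
                              draws=self.pi_draws[:, i])

    @property
    def predictions(self) -> list[RiskPrediction]:
        return [self[i] for i in range(len(self))]

    def draws_at(self, s: float) -> np.ndarray:
        return _engine.conditional_cif_extend(self._cache, s)

    def mean_at(self, s: float) -> float:
        return float(np.mean(self.draws_at(s)))

    def upper_at(self, s: float) -> float:
        return float(np.quantile(self.draws_at(s), 0.975))

    def prediction_at(self, s: float) -> RiskPrediction:
        return RiskPrediction(cause=self.cause, window=(self.t, float(s)),
                              draws=self.draws_at(s))


def predict_cif_curve(posterior: PosteriorDraws, history: PatientHistory,
                      cause: int, s_grid, rng: np.random.Generator,
                      mc_config: McConfig | None = None) -> CifCurve:
    """Estimate pi_k(t, s) on a grid of horizons with shared (theta, b)
    draws, guaranteeing per-draw monotonicity in s."""
    mc = mc_config or McConfig()
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or len(s_grid) == 0:
        raise ValueError("s_grid must be a non-empty 1-D array")
    if np.any(np.diff(s_grid) <= 0) or s_grid[0] <= history.t:
        raise ValueError("s_grid must be strictly increasing and > t")
    arr = _posterior_arrays(posterior, mc.n_theta)
    b, acc = _sample_b_batch(arr, history, rng, mc.n_b, mc)
    hb = _hazard_batch_draws(arr, b, history.baseline_covariates)
    try:
        k_idx = list(arr["cause_codes"]).index(cause)
    except ValueError:
        raise ValueError(f"unknown cause code {cause}") from None
    # refine the integration grid so panels are never wider than quad_width,
    # while keeping the requested horizons as panel boundaries
    fine = [np.array([history.t])]
    prev = history.t
    for s in s_grid:
        fine.append(panel_boundaries(prev, s, mc.quad_width)[1:])
        prev = s
    fine_grid = np.concatenate(fine)[1:]
    pi_fine, cache = _engine.conditional_cif_curve(hb, k_idx, history.t,
                                                   fine_grid, mc.cif_nodes)
    sel = np.searchsorted(fine_grid, s_grid)
    pi = pi_fine[:, sel]
    return CifCurve(cause=cause, t=history.t, s_grid=s_grid, pi_draws=pi,
                    cache=cache, acceptance_rate=acc)


def predict_cif(posterior: PosteriorDraws, history: PatientHistory,
                cause: int, s: float, rng: np.random.Generator,
                mc_config: McConfig | None = None) -> RiskPrediction:
    """Point prediction of pi_k(t, s) with posterior uncertainty."""
    if s <= history.t:
        raise ValueError("horizon s must exceed the history time t")
    curve = predict_cif_curve(posterior, history, cause, np.array([s]), rng,
                              mc_config)
    return curve[len(curve) - 1]
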