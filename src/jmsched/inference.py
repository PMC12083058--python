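"""Bayesian estimation of the joint model from training data.

The fitted model class is fixed to the structure used for risk prediction
throughout the package: per-outcome Gaussian mixed models with random
intercept and slope, Weibull cause-specific baseline hazards, baseline
covariates, and *current value* association terms with constant
coefficients.  Cause-2 coefficients are parameterized as the cause-1 value
plus a stratum offset.  The fitted class never changes with the generative
scenario -- robustness to misspecification is assessed by fitting this same
model to misspecified data.

Posterior computation works on the marginal posterior of theta: the
per-subject random effects are integrated out with a Laplace approximation.
The per-subject integrand (Gaussian prior x Gaussian longitudinal likelihood
x event term x exp(-cumulative hazard)) is log-concave in b, so the inner
Newton mode-finder is fast and reliable, and the whole marginal likelihood
is evaluated vectorized across subjects.

Two posterior modes:

* ``laplace`` (fast): MAP by L-BFGS on the marginal log-posterior, Gaussian
  posterior draws from the inverse of a finite-difference Hessian at the
  mode.  Used by the simulation study, where hundreds of refits are needed.
* ``emcee``: affine-invariant ensemble MCMC on the same marginal posterior,
  with split-Rhat / ESS diagnostics via arviz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._quad import panel_boundaries, panel_nodes
from .model_core import (AssociationTerm, CauseSpec, JointModelParams,
                         LongitudinalSpec)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the fitted joint model."""

    outcome_names: tuple[str, ...]
    covariate_names: tuple[str, ...] = ("maggic",)
    cause_codes: tuple[int, ...] = (1, 2)

    @classmethod
    def from_params(cls, params: JointModelParams) -> "ModelSpec":
        return cls(outcome_names=tuple(sp.outcome_name for sp in params.longitudinal),
                   covariate_names=tuple(params.baseline_covariate_names),
                   cause_codes=tuple(cs.cause_code for cs in params.causes))

    @property
    def n_outcomes(self) -> int:
        return len(self.outcome_names)

    @property
    def n_causes(self) -> int:
        return len(self.cause_codes)

    @property
    def n_cov(self) -> int:
        return len(self.covariate_names)

    @property
    def n_random(self) -> int:
        return 2 * self.n_outcomes


@dataclass
class McmcConfig:
    """Sampler budgets.  ``quad_panel``/``quad_nodes`` control the survival
    quadrature inside the likelihood (panels are wide here because the
    integrand exp(polynomial) is very smooth)."""

    method: str = "laplace"  # "laplace" (MAP + Gaussian draws) or "emcee"
    n_draws: int = 200
    chains: int = 2
    warmup: int = 500
    retained: int = 500
    quad_panel: float = 4.0
    quad_nodes: int = 7
    maxiter: int = 80
    ftol: float = 1e-7
    hessian_step: float = 5e-4


@dataclass
class PosteriorDraws:
    """Retained posterior draws of theta plus diagnostics."""

    draws: list[JointModelParams]
    diagnostics: dict
    chains: int
    warmup: int
    retained: int
    spec: ModelSpec | None = None
    theta: np.ndarray | None = None
    parameter_names: tuple[str, ...] = ()
    map_params: JointModelParams | None = None
    _batch_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def degenerate_posterior(params: JointModelParams, n_draws: int = 1) -> PosteriorDraws:
    """A posterior concentrated on one known theta (oracle for tests and
    self-consistency checks)."""
    return PosteriorDraws(draws=[params] * n_draws,
                          diagnostics={"method": "degenerate"},
                          chains=1, warmup=0, retained=n_draws,
                          spec=ModelSpec.from_params(params),
                          map_params=params)


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

class _Layout:
    """Index bookkeeping for the unconstrained theta vector."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        P, K, W = spec.n_outcomes, spec.n_causes, spec.n_cov
        q = spec.n_random
        names: list[str] = []
        for nm in spec.outcome_names:
            names += [f"beta_{nm}_icpt", f"beta_{nm}_time"]
        names += [f"log_sigma_{nm}" for nm in spec.outcome_names]
        names += [f"chol_logdiag_{i}" for i in range(q)]
        names += [f"chol_off_{i}_{j}" for i in range(q) for j in range(i)]
        for k in spec.cause_codes:
            names += [f"log_shape_{k}", f"log_scale_{k}"]
        for ki, k in enumerate(spec.cause_codes):
            suf = "" if ki == 0 else f"_off{k}"
            names += [f"gamma_{c}{suf}" for c in spec.covariate_names]
        for ki, k in enumerate(spec.cause_codes):
            suf = "" if ki == 0 else f"_off{k}"
            names += [f"alpha_{nm}{suf}" for nm in spec.outcome_names]
        self.names = tuple(names)
        self.P, self.K, self.W, self.q = P, K, W, q
        self.dim = len(names)
        i = 0
        self.sl_beta = slice(i, i + 2 * P); i += 2 * P
        self.sl_lsig = slice(i, i + P); i += P
        self.sl_ldiag = slice(i, i + q); i += q
        self.n_off = q * (q - 1) // 2
        self.sl_off = slice(i, i + self.n_off); i += self.n_off
        self.sl_weib = slice(i, i + 2 * K); i += 2 * K
        self.sl_gamma = slice(i, i + K * W); i += K * W
        self.sl_alpha = slice(i, i + K * P); i += K * P
        assert i == self.dim
        self._tril = np.tril_indices(q, -1)

    def unpack(self, x: np.ndarray) -> dict:
        P, K, W, q = self.P, self.K, self.W, self.q
        beta = x[self.sl_beta].reshape(P, 2)
        sigma = np.exp(x[self.sl_lsig])
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(x[self.sl_ldiag])
        L[self._tril] = x[self.sl_off]
        weib = np.exp(x[self.sl_weib]).reshape(K, 2)  # shape, scale per cause
        gamma_raw = x[self.sl_gamma].reshape(K, W)
        alpha_raw = x[self.sl_alpha].reshape(K, P)
        gamma = gamma_raw.copy()
        alpha = alpha_raw.copy()
        gamma[1:] += gamma[0]
        alpha[1:] += alpha[0]
        return {"beta": beta, "sigma": sigma, "L": L, "D": L @ L.T,
                "shapes": weib[:, 0], "scales": weib[:, 1],
                "gamma": gamma, "alpha": alpha}

    def pack(self, params: JointModelParams) -> np.ndarray:
        """theta vector for a given parameter set (value associations with
        constant coefficients only)."""
        spec = self.spec
        x = np.zeros(self.dim)
        beta = np.concatenate([np.asarray(sp.fixed_effects, dtype=float)
                               for sp in params.longitudinal])
        x[self.sl_beta] = beta
        x[self.sl_lsig] = np.log([sp.residual_sd for sp in params.longitudinal])
        L = np.linalg.cholesky(params.re_covariance
                               + 1e-10 * np.eye(self.q))
        x[self.sl_ldiag] = np.log(np.diag(L))
        x[self.sl_off] = L[self._tril]
        weib = np.array([[cs.weibull_shape, cs.weibull_scale]
                         for cs in params.causes])
        x[self.sl_weib] = np.log(weib).ravel()
        gamma = np.array([list(cs.baseline_coefficients) for cs in params.causes],
                         dtype=float).reshape(self.K, self.W)
        alpha = np.zeros((self.K, self.P))
        for ki, cs in enumerate(params.causes):
            for term in cs.association_terms:
                if term.form != "value" or term.is_time_varying:
                    raise ValueError("pack() supports constant value "
                                     "associations only")
                alpha[ki, spec.outcome_names.index(term.outcome_name)] = \
                    float(term.coefficient)
        g = gamma.copy(); g[1:] -= gamma[0]
        a = alpha.copy(); a[1:] -= alpha[0]
        x[self.sl_gamma] = g.ravel()
        x[self.sl_alpha] = a.ravel()
        return x

    def to_params(self, x: np.ndarray) -> JointModelParams:
        spec = self.spec
        u = self.unpack(x)
        longitudinal = tuple(
            LongitudinalSpec(outcome_name=nm,
                             fixed_effects=tuple(u["beta"][p]),
                             residual_sd=float(u["sigma"][p]))
            for p, nm in enumerate(spec.outcome_names))
        causes = tuple(
            CauseSpec(cause_code=code,
                      weibull_shape=float(u["shapes"][ki]),
                      weibull_scale=float(u["scales"][ki]),
                      baseline_coefficients=tuple(u["gamma"][ki]),
                      association_terms=tuple(
                          AssociationTerm(nm, "value", float(u["alpha"][ki, p]))
                          for p, nm in enumerate(spec.outcome_names)))
            for ki, code in enumerate(spec.cause_codes))
        # symmetrize against round-off so the PSD validator is happy
        D = u["D"]
        return JointModelParams(longitudinal=longitudinal,
                                re_covariance=(D + D.T) / 2,
                                causes=causes,
                                baseline_covariate_names=spec.covariate_names)


# ---------------------------------------------------------------------------
# data cache
# ---------------------------------------------------------------------------

class _DataCache:
    """theta-independent per-subject quantities: longitudinal sufficient
    statistics and survival quadrature nodes (padded to a common count)."""

    def __init__(self, long_df: pd.DataFrame, surv_df: pd.DataFrame,
                 spec: ModelSpec, quad_panel: float, quad_nodes: int):
        self.spec = spec
        surv = surv_df.reset_index(drop=True)
        ids = surv["subject_id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in survival table")
        self.subject_ids = ids
        N = len(ids)
        self.N = N
        self.T = surv["time_years"].to_numpy(dtype=float)
        codes = surv["event_code"].to_numpy(dtype=int)
        valid = set(spec.cause_codes) | {0}
        if not set(codes.tolist()) <= valid:
            raise ValueError(f"event codes must be within {sorted(valid)}")
        for k in spec.cause_codes:
            if not np.any(codes == k):
                raise ValueError(f"no events of cause {k} in the training data "
                                 "(empty event stratum)")
        self.delta = codes
        missing = [c for c in spec.covariate_names if c not in surv.columns]
        if missing:
            raise ValueError(f"survival table lacks covariate column(s) {missing}")
        self.w = surv[list(spec.covariate_names)].to_numpy(dtype=float) \
            if spec.n_cov else np.zeros((N, 0))

        # longitudinal sufficient statistics per outcome
        P = spec.n_outcomes
        self.XtX = np.zeros((P, N, 2, 2))
        self.Xty = np.zeros((P, N, 2))
        self.yty = np.zeros((P, N))
        self.nobs = np.zeros((P, N))
        grp = {k: v for k, v in long_df.groupby(["subject_id", "outcome"])}
        for i, sid in enumerate(ids):
            total = 0
            for p, nm in enumerate(spec.outcome_names):
                g = grp.get((sid, nm))
                if g is None:
                    continue
                t = g["time_years"].to_numpy(dtype=float)
                y = g["value"].to_numpy(dtype=float)
                X = np.column_stack([np.ones_like(t), t])
                self.XtX[p, i] = X.T @ X
                self.Xty[p, i] = X.T @ y
                self.yty[p, i] = y @ y
                self.nobs[p, i] = len(y)
                total += len(y)
            if total == 0:
                raise ValueError(f"subject {sid} has no longitudinal records")

        # survival quadrature nodes on [0, T_i], padded
        node_list, weight_list = [], []
        for i in range(N):
            b = panel_boundaries(0.0, self.T[i], quad_panel)
            tt, ww = panel_nodes(b, quad_nodes)
            node_list.append(tt.ravel())
            weight_list.append(ww.ravel())
        Q = max(len(v) for v in node_list)
        self.tq = np.ones((N, Q))
        self.wq = np.zeros((N, Q))
        for i, (tt, ww) in enumerate(zip(node_list, weight_list)):
            self.tq[i, :len(tt)] = tt
            self.wq[i, :len(ww)] = ww
        self.log_tq = np.log(self.tq)
        self.log_T = np.log(np.maximum(self.T, 1e-12))
        self.b_hat = np.zeros((N, spec.n_random))


# ---------------------------------------------------------------------------
# marginal log-likelihood (Laplace over b)
# ---------------------------------------------------------------------------

def _marginal_loglik(cache: _DataCache, u: dict, newton_tol: float = 1e-8,
                     max_newton: int = 60) -> float:
    """Sum over subjects of log integral p(y_i, T_i, delta_i | b) p(b) db,
    each integral approximated by Laplace at the (unique) mode of the
    log-concave integrand."""
    spec = cache.spec
    P, K, q, N = spec.n_outcomes, spec.n_causes, spec.n_random, cache.N
    beta, sigma = u["beta"], u["sigma"]
    alpha, gamma = u["alpha"], u["gamma"]
    shapes, scales = u["shapes"], u["scales"]
    D = u["D"]
    try:
        Dch = np.linalg.cholesky(D + 1e-12 * np.eye(q))
    except np.linalg.LinAlgError:
        return -np.inf
    Dinv = np.linalg.inv(D + 1e-12 * np.eye(q))
    logdetD = 2.0 * np.sum(np.log(np.diag(Dch)))

    # longitudinal quadratics
    inv_s2 = 1.0 / sigma**2
    qv = np.zeros((N, q))
    A = np.zeros((N, q, q))
    const = np.zeros(N)  # per-subject b-free longitudinal terms
    for p in range(P):
        sl = slice(2 * p, 2 * p + 2)
        resid_proj = cache.Xty[p] - cache.XtX[p] @ beta[p]
        qv[:, sl] = resid_proj * inv_s2[p]
        A[:, sl, sl] = cache.XtX[p] * inv_s2[p]
        c0 = (cache.yty[p] - 2.0 * cache.Xty[p] @ beta[p]
              + beta[p] @ cache.XtX[p] @ beta[p])
        const += -0.5 * c0 * inv_s2[p] \
                 - 0.5 * cache.nobs[p] * (_LOG2PI + 2.0 * np.log(sigma[p]))

    # survival: b-independent exponent at the quadrature nodes and at T
    gw = cache.w @ gamma.T  # (N, K)
    ce = np.empty((K, N, cache.tq.shape[1]))
    ceT = np.empty((K, N))
    for k in range(K):
        base_q = (np.log(shapes[k]) - shapes[k] * np.log(scales[k])
                  + (shapes[k] - 1.0) * cache.log_tq)
        fx_q = sum(alpha[k, p] * (beta[p, 0] + beta[p, 1] * cache.tq)
                   for p in range(P))
        ce[k] = base_q + gw[:, k][:, None] + fx_q
        base_T = (np.log(shapes[k]) - shapes[k] * np.log(scales[k])
                  + (shapes[k] - 1.0) * cache.log_T)
        fx_T = sum(alpha[k, p] * (beta[p, 0] + beta[p, 1] * cache.T)
                   for p in range(P))
        ceT[k] = base_T + gw[:, k] + fx_T

    ev_mask = np.zeros((K, N))
    for ki, code in enumerate(spec.cause_codes):
        ev_mask[ki] = cache.delta == code

    tq, wq, T = cache.tq, cache.wq, cache.T

    def f_and_derivs(b, want_derivs=True):
        # b: (N, q). Returns f (N,), grad (N,q), hess (N,q,q)
        uvals = np.stack([b[:, 2 * p, None] + b[:, 2 * p + 1, None] * tq
                          for p in range(P)])  # (P, N, Q)
        uT = np.stack([b[:, 2 * p] + b[:, 2 * p + 1] * T for p in range(P)])
        f = const + np.einsum("nq,nq->n", b, qv) \
            - 0.5 * np.einsum("ni,nij,nj->n", b, A, b) \
            - 0.5 * np.einsum("ni,ij,nj->n", b, Dinv, b) \
            - 0.5 * (logdetD + q * _LOG2PI)
        grad = hess = None
        if want_derivs:
            grad = qv - np.einsum("nij,nj->ni", A, b) - b @ Dinv
            hess = -(A + Dinv[None]).copy()
        for k in range(K):
            expnt = ce[k] + sum(alpha[k, p] * uvals[p] for p in range(P))
            E = wq * np.exp(np.clip(expnt, None, 200.0))  # (N, Q)
            S0 = E.sum(axis=1)
            f -= S0
            lin_T = ceT[k] + sum(alpha[k, p] * uT[p] for p in range(P))
            f += ev_mask[k] * lin_T
            if want_derivs:
                S1 = (E * tq).sum(axis=1)
                S2 = (E * tq * tq).sum(axis=1)
                for p in range(P):
                    grad[:, 2 * p] += alpha[k, p] * (ev_mask[k] - S0)
                    grad[:, 2 * p + 1] += alpha[k, p] * (ev_mask[k] * T - S1)
                    for p2 in range(P):
                        aa = alpha[k, p] * alpha[k, p2]
                        hess[:, 2 * p, 2 * p2] -= aa * S0
                        hess[:, 2 * p, 2 * p2 + 1] -= aa * S1
                        hess[:, 2 * p + 1, 2 * p2] -= aa * S1
                        hess[:, 2 * p + 1, 2 * p2 + 1] -= aa * S2
        return f, grad, hess

    b = cache.b_hat.copy()
    f, grad, hess = f_and_derivs(b)
    for _ in range(max_newton):
        gmax = np.max(np.abs(grad))
        if gmax < newton_tol:
            break
        H = hess - 1e-10 * np.eye(q)[None]
        try:
            step = np.linalg.solve(-H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return -np.inf
        scale_step = np.ones((N, 1))
        for _ls in range(12):
            b_new = b + scale_step * step
            f_new, _, _ = f_and_derivs(b_new, want_derivs=False)
            worse = ~(f_new >= f - 1e-12)
            if not np.any(worse):
                break
            scale_step[worse] *= 0.5
        accept = f_new >= f - 1e-12
        if not np.any(accept):
            break
        b = np.where(accept[:, None], b_new, b)
        f_chk, grad, hess = f_and_derivs(b)
        f = f_chk
    cache.b_hat = b

    negH = -hess
    sign, logdet = np.linalg.slogdet(negH)
    if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
        return -np.inf
    ll = f + 0.5 * q * _LOG2PI - 0.5 * logdet
    total = float(np.sum(ll))
    return total if np.isfinite(total) else -np.inf


def _log_prior(x: np.ndarray, lay: _Layout) -> float:
    lp = 0.0
    lp += -0.5 * np.sum(x[lay.sl_beta] ** 2) / 100.0
    lp += -0.5 * np.sum(x[lay.sl_gamma] ** 2) / 100.0
    lp += -0.5 * np.sum(x[lay.sl_alpha] ** 2) / 100.0
    lp += -0.5 * np.sum(x[lay.sl_lsig] ** 2) / 25.0
    lp += -0.5 * np.sum(x[lay.sl_weib] ** 2) / 25.0
    # Cholesky-factor prior: half-normal(0, 2^2) on the diagonals (with the
    # exp-transform Jacobian), standard normal on the off-diagonals
    ld = x[lay.sl_ldiag]
    lp += np.sum(-0.5 * np.exp(2 * ld) / 4.0 + ld)
    lp += -0.5 * np.sum(x[lay.sl_off] ** 2)
    return float(lp)


def make_log_posterior(long_df: pd.DataFrame, surv_df: pd.DataFrame,
                       spec: ModelSpec, mcmc: McmcConfig):
    """Build (log_posterior(x), layout, cache) for the marginal posterior."""
    lay = _Layout(spec)
    cache = _DataCache(long_df, surv_df, spec, mcmc.quad_panel, mcmc.quad_nodes)

    def log_post(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 50:
            return -np.inf
        u = lay.unpack(x)
        ll = _marginal_loglik(cache, u)
        if not np.isfinite(ll):
            return -np.inf
        return ll + _log_prior(x, lay)

    return log_post, lay, cache


# ---------------------------------------------------------------------------
# longitudinal-only fit (exact marginal Gaussian likelihood)
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalFit:
    beta: np.ndarray          # (P, 2)
    sigma: np.ndarray         # (P,)
    re_covariance: np.ndarray
    loglik: float
    x: np.ndarray
    names: tuple[str, ...]


def _lmm_loglik(cache: _DataCache, u: dict) -> float:
    """Exact marginal Gaussian log-likelihood (Woodbury on the per-subject
    sufficient statistics); independent of the Laplace code path."""
    spec = cache.spec
    P, q, N = spec.n_outcomes, spec.n_random, cache.N
    beta, sigma, D = u["beta"], u["sigma"], u["D"]
    Dj = D + 1e-12 * np.eye(q)
    sign, logdetD = np.linalg.slogdet(Dj)
    if sign <= 0:
        return -np.inf
    Dinv = np.linalg.inv(Dj)
    inv_s2 = 1.0 / sigma**2
    qv = np.zeros((N, q))
    A = np.zeros((N, q, q))
    const = 0.0
    for p in range(P):
        sl = slice(2 * p, 2 * p + 2)
        qv[:, sl] = (cache.Xty[p] - cache.XtX[p] @ beta[p]) * inv_s2[p]
        A[:, sl, sl] = cache.XtX[p] * inv_s2[p]
        c0 = (cache.yty[p] - 2.0 * cache.Xty[p] @ beta[p]
              + beta[p] @ cache.XtX[p] @ beta[p])
        const += -0.5 * float(np.sum(c0)) * inv_s2[p] \
                 - 0.5 * float(np.sum(cache.nobs[p])) * (_LOG2PI + 2.0 * np.log(sigma[p]))
    M = A + Dinv[None]
    sign_m, logdet_m = np.linalg.slogdet(M)
    if np.any(sign_m <= 0):
        return -np.inf
    sol = np.linalg.solve(M, qv[..., None])[..., 0]
    quad = np.einsum("nq,nq->n", qv, sol)
    ll = const + 0.5 * float(np.sum(quad)) \
        - 0.5 * N * logdetD - 0.5 * float(np.sum(logdet_m))
    return ll if np.isfinite(ll) else -np.inf


def fit_longitudinal_only(long_df: pd.DataFrame, surv_df: pd.DataFrame,
                          spec: ModelSpec, maxiter: int = 300) -> LongitudinalFit:
    """Maximum-likelihood linear mixed model for the longitudinal submodels
    alone (association fixed at zero, survival ignored)."""
    mcmc = McmcConfig()
    lay = _Layout(spec)
    cache = _DataCache(long_df, surv_df, spec, mcmc.quad_panel, mcmc.quad_nodes)
    x0 = _init_theta(cache, lay)
    idx = np.r_[np.arange(lay.sl_beta.start, lay.sl_beta.stop),
                np.arange(lay.sl_lsig.start, lay.sl_lsig.stop),
                np.arange(lay.sl_ldiag.start, lay.sl_ldiag.stop),
                np.arange(lay.sl_off.start, lay.sl_off.stop)]

    def neg(z):
        x = x0.copy()
        x[idx] = z
        return -_lmm_loglik(cache, lay.unpack(x))

    res = optimize.minimize(neg, x0[idx], method="L-BFGS-B",
                            options={"maxiter": maxiter, "eps": 1e-6})
    x = x0.copy()
    x[idx] = res.x
    u = lay.unpack(x)
    return LongitudinalFit(beta=u["beta"], sigma=u["sigma"],
                           re_covariance=u["D"], loglik=-res.fun, x=x,
                           names=lay.names)


def _init_theta(cache: _DataCache, lay: _Layout) -> np.ndarray:
    """Cheap starting values: pooled OLS per outcome, diagonal D guess,
    exponential baselines matching crude event rates, zero associations."""
    spec = cache.spec
    x = np.zeros(lay.dim)
    sig0 = np.zeros(spec.n_outcomes)
    for p in range(spec.n_outcomes):
        XtX = cache.XtX[p].sum(axis=0)
        Xty = cache.Xty[p].sum(axis=0)
        beta = np.linalg.solve(XtX + 1e-8 * np.eye(2), Xty)
        n = cache.nobs[p].sum()
        sse = cache.yty[p].sum() - beta @ Xty
        sig0[p] = np.sqrt(max(sse / max(n, 1), 1e-4))
        x[lay.sl_beta][2 * p:2 * p + 2] = beta
        # pooled residual SD overstates sigma (it absorbs between-subject
        # spread); start D diagonals at half of it
        x[lay.sl_lsig][p] = np.log(sig0[p] * 0.7)
        x[lay.sl_ldiag][2 * p] = np.log(max(sig0[p] * 0.7, 1e-3))
        x[lay.sl_ldiag][2 * p + 1] = np.log(0.05)
    total_T = float(np.sum(cache.T))
    for ki, code in enumerate(spec.cause_codes):
        d = max(int(np.sum(cache.delta == code)), 1)
        x[lay.sl_weib][2 * ki] = 0.0                      # shape 1
        x[lay.sl_weib][2 * ki + 1] = np.log(total_T / d)  # scale
    return x


def _eb_random_effects(cache: _DataCache, u: dict) -> np.ndarray:
    """Empirical-Bayes modes of b from the longitudinal part alone."""
    spec = cache.spec
    P, q, N = spec.n_outcomes, spec.n_random, cache.N
    beta, sigma, D = u["beta"], u["sigma"], u["D"]
    Dinv = np.linalg.inv(D + 1e-12 * np.eye(q))
    inv_s2 = 1.0 / sigma**2
    qv = np.zeros((N, q))
    A = np.zeros((N, q, q))
    for p in range(P):
        sl = slice(2 * p, 2 * p + 2)
        qv[:, sl] = (cache.Xty[p] - cache.XtX[p] @ beta[p]) * inv_s2[p]
        A[:, sl, sl] = cache.XtX[p] * inv_s2[p]
    return np.linalg.solve(A + Dinv[None], qv[..., None])[..., 0]


def _survival_stage_loglik(cache: _DataCache, u: dict, b: np.ndarray) -> float:
    """Survival log-likelihood with random effects plugged in (two-stage
    initialization; no marginalization)."""
    spec = cache.spec
    P, K = spec.n_outcomes, spec.n_causes
    beta, alpha, gamma = u["beta"], u["alpha"], u["gamma"]
    shapes, scales = u["shapes"], u["scales"]
    gw = cache.w @ gamma.T
    tq, wq, T = cache.tq, cache.wq, cache.T
    ll = 0.0
    for k in range(K):
        eta_q = sum(alpha[k, p] * (beta[p, 0] + b[:, 2 * p, None]
                                   + (beta[p, 1] + b[:, 2 * p + 1, None]) * tq)
                    for p in range(P))
        base_q = (np.log(shapes[k]) - shapes[k] * np.log(scales[k])
                  + (shapes[k] - 1.0) * cache.log_tq)
        H = (wq * np.exp(np.clip(base_q + gw[:, k][:, None] + eta_q, None, 200.0))).sum(axis=1)
        eta_T = sum(alpha[k, p] * (beta[p, 0] + b[:, 2 * p]
                                   + (beta[p, 1] + b[:, 2 * p + 1]) * T)
                    for p in range(P))
        log_h_T = (np.log(shapes[k]) - shapes[k] * np.log(scales[k])
                   + (shapes[k] - 1.0) * cache.log_T + gw[:, k] + eta_T)
        ev = cache.delta == spec.cause_codes[k]
        ll += float(np.sum(ev * log_h_T) - np.sum(H))
    return ll if np.isfinite(ll) else -np.inf


def _numeric_hessian(fn, x: np.ndarray, step: float) -> np.ndarray:
    """Finite-difference Hessian: central on the diagonal, forward cross
    terms (n^2/2 + 2n evaluations)."""
    n = len(x)
    H = np.zeros((n, n))
    h = step * (1.0 + np.abs(x))
    f0 = fn(x)
    fp = np.zeros(n)
    for i in range(n):
        e = np.zeros(n); e[i] = h[i]
        fp[i] = fn(x + e)
        fm = fn(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm) / h[i] ** 2
    for i in range(n):
        for j in range(i):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fn(x + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    return H


def _rhat_ess(theta_chains: np.ndarray, names) -> tuple[dict, dict]:
    """Split-Rhat and bulk ESS per scalar parameter via arviz.

    theta_chains: (chains, draws, dim)."""
    import arviz as az
    data = {nm: theta_chains[:, :, i] for i, nm in enumerate(names)}
    idata = az.convert_to_dataset(data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    return ({nm: float(rhat[nm].values) for nm in names},
            {nm: float(ess[nm].values) for nm in names})


def fit_joint_model(train_longitudinal: pd.DataFrame,
                    train_survival: pd.DataFrame,
                    model_spec: ModelSpec,
                    mcmc_config: McmcConfig | None = None,
                    rng: np.random.Generator | None = None) -> PosteriorDraws:
    """Posterior draws of theta given long-format training data.

    ``train_survival`` must carry one row per subject with columns
    (subject_id, time_years, event_code, <covariates...>).
    """
    mcmc = mcmc_config or McmcConfig()
    rng = rng or np.random.default_rng()
    log_post, lay, cache = make_log_posterior(train_longitudinal,
                                              train_survival, model_spec, mcmc)

    # stage 1: longitudinal-only ML to seed the joint mode search
    lfit = fit_longitudinal_only(train_longitudinal, train_survival, model_spec)
    x0 = lfit.x.copy()
    x0_haz = _init_theta(cache, lay)
    x0[lay.sl_weib] = x0_haz[lay.sl_weib]

    # stage 2: survival parameters with empirical-Bayes b plugged in; cheap
    # because no marginalization is needed, and it puts the joint mode search
    # within a few L-BFGS steps of the answer
    b_eb = _eb_random_effects(cache, lay.unpack(x0))
    idx_surv = np.r_[np.arange(lay.sl_weib.start, lay.sl_weib.stop),
                     np.arange(lay.sl_gamma.start, lay.sl_gamma.stop),
                     np.arange(lay.sl_alpha.start, lay.sl_alpha.stop)]

    def neg_surv(z):
        x = x0.copy()
        x[idx_surv] = z
        return -_survival_stage_loglik(cache, lay.unpack(x), b_eb) \
            - _log_prior(x, lay)

    res_s = optimize.minimize(neg_surv, x0[idx_surv], method="L-BFGS-B",
                              options={"maxiter": 200, "eps": 1e-6})
    x0[idx_surv] = res_s.x
    cache.b_hat = b_eb.copy()

    res = optimize.minimize(lambda z: -log_post(z), x0, method="L-BFGS-B",
                            options={"maxiter": mcmc.maxiter, "eps": 1e-6,
                                     "ftol": mcmc.ftol,
                                     "maxfun": mcmc.maxiter * 40})
    x_map = res.x
    if not res.success:
        logger.warning("MAP optimization did not report convergence: %s",
                       res.message)

    diagnostics: dict = {"method": mcmc.method, "map_converged": bool(res.success),
                         "neg_log_posterior": float(res.fun)}

    if mcmc.method == "laplace":
        H = _numeric_hessian(lambda z: -log_post(z), x_map, mcmc.hessian_step)
        evals, evecs = np.linalg.eigh((H + H.T) / 2)
        evals = np.clip(evals, 1e-6, None)
        cov = (evecs / evals) @ evecs.T
        Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(lay.dim))
        n = mcmc.n_draws
        theta = x_map[None, :] + rng.standard_normal((n, lay.dim)) @ Lc.T
        # guard against absurd draws when a direction is barely identified
        # (tiny curvature clipped above): exp-transformed parameters must not
        # overflow downstream
        theta = np.clip(theta, -30.0, 30.0)
        pseudo = theta.reshape(2, n // 2, lay.dim) if n >= 4 else theta[None]
        rhat, ess = _rhat_ess(pseudo, lay.names)
        diagnostics.update({"rhat": rhat, "ess": ess,
                            "posterior_sd": dict(zip(lay.names,
                                                     np.sqrt(np.diag(cov))))})
        chains, warmup, retained = 1, 0, n
    elif mcmc.method == "emcee":
        import emcee
        nwalkers = max(2 * lay.dim + 4, 8 * mcmc.chains)
        p0 = x_map[None, :] + 1e-3 * rng.standard_normal((nwalkers, lay.dim))
        sampler = emcee.EnsembleSampler(nwalkers, lay.dim, log_post)
        rstate = np.random.RandomState(int(rng.integers(2**31))).get_state()
        sampler.run_mcmc(p0, mcmc.warmup + mcmc.retained, progress=False,
                         rstate0=rstate, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=mcmc.warmup)  # (steps, walkers, dim)
        theta_chains = np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)
        rhat, ess = _rhat_ess(theta_chains, lay.names)
        flat = chain.reshape(-1, lay.dim)
        take = np.linspace(0, len(flat) - 1, min(mcmc.n_draws, len(flat))).astype(int)
        theta = flat[take]
        frac_bad = np.mean([v > 1.1 for v in rhat.values()])
        if frac_bad > 0.05:
            logger.warning("%.0f%% of parameters have Rhat > 1.1", 100 * frac_bad)
        diagnostics.update({"rhat": rhat, "ess": ess,
                            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
                            "rhat_flagged_fraction": float(frac_bad)})
        chains, warmup, retained = nwalkers, mcmc.warmup, chain.shape[0]
    else:
        raise ValueError(f"unknown method {mcmc.method!r}")

    draws = [lay.to_params(theta[i]) for i in range(theta.shape[0])]
    if len(draws) < 200:
        logger.warning("only %d retained draws; downstream prediction "
                       "recommends >= 200", len(draws))
    return PosteriorDraws(draws=draws, diagnostics=diagnostics, chains=chains,
                          warmup=warmup, retained=retained, spec=model_spec,
                          theta=theta, parameter_names=lay.names,
                          map_params=lay.to_params(x_map))
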