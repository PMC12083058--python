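"""Joint-model parameterization and deterministic model mathematics.

The model couples P Gaussian mixed-effects biomarker submodels

    eta_p(t) = x_p(t)' beta_p + z_p(t)' b_p,      y_p(t) = eta_p(t) + eps_p,

with K cause-specific proportional hazards

    h_k(t) = h_k0(t) * exp( gamma_k' w + sum_j alpha_kj(t) * f_kj(t) ),

where h_k0 is Weibull with hazard (shape/scale) * (t/scale)^(shape-1), w are
baseline covariates (here the MAGGIC clinical risk score), and each
association term f_kj is the current value, slope, or area under the curve of
one biomarker's subject-specific linear predictor.  The stacked random
effects b = (b_1', ..., b_P')' are multivariate normal with covariance D.

Design bases are monomials in time (intercept + slope by default), which
makes value/slope/area association forms closed-form polynomials in t; all
survival integrals then reduce to smooth integrands handled by fixed-panel
Gauss-Legendre quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from ._quad import QuadratureRule, panel_boundaries

DEFAULT_QUAD = QuadratureRule(panel_width=0.5, n_nodes=15)

ASSOCIATION_FORMS = ("value", "slope", "area")


class UnknownOutcomeError(KeyError):
    """Raised when an outcome label is not declared in the parameters."""


@dataclass(frozen=True)
class LongitudinalSpec:
    """One biomarker submodel.

    ``fixed_design`` / ``random_design`` are tuples of monomial powers of
    time; the default (0, 1) encodes intercept + slope.  ``fixed_effects``
    aligns with ``fixed_design``.  ``residual_sd`` is on the (log) scale of
    the outcome.
    """

    outcome_name: str
    fixed_effects: tuple[float, ...]
    residual_sd: float
    fixed_design: tuple[int, ...] = (0, 1)
    random_design: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(f"{self.outcome_name}: residual_sd must be > 0")
        if len(self.fixed_design) < 1 or len(self.random_design) < 1:
            raise ValueError("designs need at least one basis function")
        if len(self.fixed_effects) != len(self.fixed_design):
            raise ValueError("fixed_effects length must match fixed_design")
        if not set(self.random_design) <= set(self.fixed_design):
            raise ValueError("random_design must be a subset of fixed_design")

    @property
    def n_random(self) -> int:
        return len(self.random_design)


@dataclass(frozen=True)
class AssociationTerm:
    """One hazard association term alpha(t) * f(eta).

    ``coefficient`` is a float (constant alpha) or a tuple of polynomial
    coefficients in t, lowest order first (time-varying alpha, generative
    role only).
    """

    outcome_name: str
    form: str = "value"
    coefficient: float | tuple[float, ...] = 0.0

    def __post_init__(self) -> None:
        if self.form not in ASSOCIATION_FORMS:
            raise ValueError(f"association form must be one of {ASSOCIATION_FORMS}")

    @property
    def coefficient_poly(self) -> np.ndarray:
        c = self.coefficient
        return np.atleast_1d(np.asarray(c, dtype=float))

    @property
    def is_time_varying(self) -> bool:
        return self.coefficient_poly.size > 1

    def coefficient_at(self, t: float) -> float:
        c = self.coefficient_poly
        return float(np.polynomial.polynomial.polyval(t, c))


@dataclass(frozen=True)
class CauseSpec:
    """One competing cause: Weibull baseline, baseline-covariate coefficients
    gamma, and association terms."""

    cause_code: int
    weibull_shape: float
    weibull_scale: float
    baseline_coefficients: tuple[float, ...] = ()
    association_terms: tuple[AssociationTerm, ...] = ()

    def __post_init__(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")


@dataclass(frozen=True)
class JointModelParams:
    """Complete generative/fitted parameter set theta."""

    longitudinal: tuple[LongitudinalSpec, ...]
    re_covariance: np.ndarray
    causes: tuple[CauseSpec, ...]
    baseline_covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        D = np.asarray(self.re_covariance, dtype=float)
        object.__setattr__(self, "re_covariance", D)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("re_covariance must be square")
        scale = max(1.0, float(np.max(np.abs(D))))
        if not np.allclose(D, D.T, atol=1e-9 * scale):
            raise ValueError("re_covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(D)) < -1e-9 * scale:
            raise ValueError("re_covariance must be positive semi-definite")
        if D.shape[0] != self.n_random_effects:
            raise ValueError("re_covariance dimension must match the total "
                             "number of random-design basis functions")
        if len(self.causes) < 1:
            raise ValueError("need at least one cause")
        declared = {sp.outcome_name for sp in self.longitudinal}
        for cs in self.causes:
            for term in cs.association_terms:
                if term.outcome_name not in declared:
                    raise UnknownOutcomeError(term.outcome_name)
            if len(cs.baseline_coefficients) != len(self.baseline_covariate_names):
                raise ValueError("baseline_coefficients length must match "
                                 "baseline_covariate_names")

    @property
    def n_random_effects(self) -> int:
        return sum(sp.n_random for sp in self.longitudinal)

    @property
    def n_causes(self) -> int:
        return len(self.causes)

    def outcome_index(self, name: str) -> int:
        for i, sp in enumerate(self.longitudinal):
            if sp.outcome_name == name:
                return i
        raise UnknownOutcomeError(name)

    def random_slice(self, name: str) -> slice:
        """Position of an outcome's random effects in the stacked b vector."""
        off = 0
        for sp in self.longitudinal:
            if sp.outcome_name == name:
                return slice(off, off + sp.n_random)
            off += sp.n_random
        raise UnknownOutcomeError(name)

    def cause(self, code: int) -> CauseSpec:
        for cs in self.causes:
            if cs.cause_code == code:
                return cs
        raise ValueError(f"unknown cause code {code}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "longitudinal": [
                {"outcome_name": sp.outcome_name,
                 "fixed_effects": list(sp.fixed_effects),
                 "residual_sd": sp.residual_sd,
                 "fixed_design": list(sp.fixed_design),
                 "random_design": list(sp.random_design)}
                for sp in self.longitudinal],
            "re_covariance": [[float(v) for v in row] for row in self.re_covariance],
            "causes": [
                {"cause_code": cs.cause_code,
                 "weibull_shape": cs.weibull_shape,
                 "weibull_scale": cs.weibull_scale,
                 "baseline_coefficients": list(cs.baseline_coefficients),
                 "association_terms": [
                     {"outcome_name": at.outcome_name, "form": at.form,
                      "coefficient": (list(at.coefficient)
                                      if isinstance(at.coefficient, (tuple, list))
                                      else at.coefficient)}
                     for at in cs.association_terms]}
                for cs in self.causes],
            "baseline_covariate_names": list(self.baseline_covariate_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointModelParams":
        longitudinal = tuple(
            LongitudinalSpec(outcome_name=sp["outcome_name"],
                             fixed_effects=tuple(sp["fixed_effects"]),
                             residual_sd=float(sp["residual_sd"]),
                             fixed_design=tuple(sp.get("fixed_design", (0, 1))),
                             random_design=tuple(sp.get("random_design", (0, 1))))
            for sp in d["longitudinal"])
        causes = tuple(
            CauseSpec(cause_code=int(cs["cause_code"]),
                      weibull_shape=float(cs["weibull_shape"]),
                      weibull_scale=float(cs["weibull_scale"]),
                      baseline_coefficients=tuple(cs.get("baseline_coefficients", ())),
                      association_terms=tuple(
                          AssociationTerm(outcome_name=at["outcome_name"],
                                          form=at.get("form", "value"),
                                          coefficient=(tuple(at["coefficient"])
                                                       if isinstance(at["coefficient"], list)
                                                       else float(at["coefficient"])))
                          for at in cs.get("association_terms", ())))
            for cs in d["causes"])
        return cls(longitudinal=longitudinal,
                   re_covariance=np.asarray(d["re_covariance"], dtype=float),
                   causes=causes,
                   baseline_covariate_names=tuple(d.get("baseline_covariate_names", ())))


@dataclass
class SubjectTruth:
    """Latent state of one simulated patient.

    ``true_event_time``/``true_cause`` are the observed (post administrative
    censoring) failure time and cause; cause 0 means censored at the 20-year
    horizon.  They remain None until an event time has been sampled.
    """

    subject_id: str
    random_effects: np.ndarray
    baseline_covariates: np.ndarray
    true_event_time: float | None = None
    true_cause: int | None = None

    def __post_init__(self) -> None:
        self.random_effects = np.asarray(self.random_effects, dtype=float)
        self.baseline_covariates = np.atleast_1d(
            np.asarray(self.baseline_covariates, dtype=float))


# ---------------------------------------------------------------------------
# hazard-batch construction
# ---------------------------------------------------------------------------

def eta_poly(params: JointModelParams, b: np.ndarray, outcome: str) -> np.ndarray:
    """Polynomial coefficients (lowest first) of eta(t) for one outcome."""
    i = params.outcome_index(outcome)
    sp = params.longitudinal[i]
    b = np.asarray(b, dtype=float)
    bo = b[params.random_slice(outcome)]
    deg = max(sp.fixed_design)
    coef = np.zeros(deg + 1)
    for pw, beta in zip(sp.fixed_design, sp.fixed_effects):
        coef[pw] += beta
    for pw, bv in zip(sp.random_design, bo):
        coef[pw] += bv
    return coef


def _term_poly(params: JointModelParams, b: np.ndarray,
               term: AssociationTerm) -> np.ndarray:
    """Polynomial coefficients of alpha(t) * f(eta) for one association term."""
    eta = eta_poly(params, b, term.outcome_name)
    if term.form == "value":
        f = eta
    elif term.form == "slope":
        f = np.polynomial.polynomial.polyder(eta) if len(eta) > 1 else np.zeros(1)
    else:  # area: closed-form antiderivative of eta, zero at t = 0
        f = np.polynomial.polynomial.polyint(eta)
    return np.polynomial.polynomial.polymul(term.coefficient_poly, f)


def hazard_batch(params: JointModelParams, b_batch: np.ndarray,
                 w_batch: np.ndarray) -> _engine.HazardBatch:
    """Build the vectorized hazard representation for a batch of subjects
    sharing theta.  b_batch: (N, q); w_batch: (N, n_cov)."""
    b_batch = np.atleast_2d(np.asarray(b_batch, dtype=float))
    w_batch = np.asarray(w_batch, dtype=float)
    if w_batch.ndim == 1:
        w_batch = w_batch[:, None] if len(params.baseline_covariate_names) == 1 \
            else np.atleast_2d(w_batch)
    N = b_batch.shape[0]
    K = params.n_causes
    polys: list[list[np.ndarray]] = []
    maxdeg = 0
    for cs in params.causes:
        row = []
        for i in range(N):
            p = np.zeros(1)
            for term in cs.association_terms:
                p = np.polynomial.polynomial.polyadd(
                    p, _term_poly(params, b_batch[i], term))
            if len(cs.baseline_coefficients):
                p = p.copy()
                p[0] += float(np.dot(cs.baseline_coefficients, w_batch[i]))
            row.append(p)
            maxdeg = max(maxdeg, len(p) - 1)
        polys.append(row)
    expo = np.zeros((K, N, maxdeg + 1))
    for k in range(K):
        for i in range(N):
            p = polys[k][i]
            expo[k, i, :len(p)] = p
    shapes = np.array([[cs.weibull_shape] * N for cs in params.causes])
    scales = np.array([[cs.weibull_scale] * N for cs in params.causes])
    return _engine.HazardBatch(shapes=shapes, scales=scales, expo=expo)


def _subject_batch(params: JointModelParams, subject: SubjectTruth) -> _engine.HazardBatch:
    return hazard_batch(params, subject.random_effects[None, :],
                        subject.baseline_covariates[None, :])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def linear_predictor(params: JointModelParams, b: np.ndarray, outcome: str,
                     t: float | np.ndarray) -> float | np.ndarray:
    """x(t)'beta + z(t)'b for the named outcome; vectorized over t."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    coef = eta_poly(params, b, outcome)
    out = np.polynomial.polynomial.polyval(t, coef)
    return float(out) if out.ndim == 0 else out


def cause_specific_hazard(params: JointModelParams, subject: SubjectTruth,
                          cause: int, t: float) -> float:
    """h_k0(t) * exp(gamma_k'w + sum_j alpha_kj(t) f_kj(t))."""
    cs = params.cause(cause)
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        if cs.weibull_shape < 1:
            raise ValueError("hazard unbounded at t = 0 for Weibull shape < 1")
        if cs.weibull_shape > 1:
            return 0.0
        # shape == 1: h0 = 1/scale; covariate terms evaluated at 0
        hb = _subject_batch(params, subject)
        k = [c.cause_code for c in params.causes].index(cause)
        return float(np.exp(hb.expo[k, 0, 0]) / cs.weibull_scale)
    hb = _subject_batch(params, subject)
    k = [c.cause_code for c in params.causes].index(cause)
    return float(_engine.hazards_at(hb, np.array([t]))[k, 0, 0])


def cumulative_overall_hazard(params: JointModelParams, subject: SubjectTruth,
                              t: float, quad: QuadratureRule = DEFAULT_QUAD) -> float:
    """H(t) = sum_k int_0^t h_k(u) du by panel Gauss-Legendre quadrature."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    hb = _subject_batch(params, subject)
    bounds = panel_boundaries(0.0, t, quad.panel_width)
    H = _engine.cumhaz_at_boundaries(hb, bounds, quad.n_nodes).sum(axis=0)
    return float(H[0, -1])


def overall_survival(params: JointModelParams, subject: SubjectTruth,
                     t: float, quad: QuadratureRule = DEFAULT_QUAD) -> float:
    """S(t) = exp(-H(t))."""
    return float(np.exp(-cumulative_overall_hazard(params, subject, t, quad)))


def true_conditional_cif(params: JointModelParams, subject: SubjectTruth,
                         cause: int, t: float, s: float,
                         quad: QuadratureRule = DEFAULT_QUAD) -> float:
    """Conditional cumulative incidence int_t^s h_k(u) S(u) du / S(t).

    Equals the probability of failing from cause k in (t, s] given survival
    of all causes past t.
    """
    if not 0 <= t <= s:
        raise ValueError("need 0 <= t <= s")
    if s == t:
        return 0.0
    if t > 0:
        Ht = cumulative_overall_hazard(params, subject, t, quad)
        if Ht > _engine._EXP_CLIP:
            raise FloatingPointError("S(t) underflows to 0; conditioning undefined")
    hb = _subject_batch(params, subject)
    k = [c.cause_code for c in params.causes].index(cause)
    s_grid = panel_boundaries(t, s, quad.panel_width)[1:]
    pi, _ = _engine.conditional_cif_curve(hb, k, t, s_grid,
                                          n_nodes=min(quad.n_nodes, 10))
    return float(pi[0, -1])
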