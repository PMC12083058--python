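"""Vectorized cause-specific-hazard engine.

A batch of hazard specifications (one element per simulated subject, or per
posterior draw in dynamic prediction) is reduced to, for each cause k,

    log h_k(t) = log(a_k) - a_k*log(s_k) + (a_k - 1)*log(t) + P_k(t)

where (a_k, s_k) are the Weibull shape/scale of the baseline hazard and
P_k(t) is a batch of low-degree polynomials collecting the baseline-covariate
term gamma_k'w and every association term alpha_kj(t) * f_kj(t).  With linear
mixed-effect trajectories eta(t), the value / slope / area association forms
(and polynomial time-varying coefficients) are all polynomial in t, so this
representation is exact.

All integrals are composite Gauss-Legendre on fixed panels (see _quad);
cumulative-incidence integrals use a nested rule for the inner survival
integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quad import QuadratureRule, interval_nodes, panel_boundaries, panel_nodes

_EXP_CLIP = 700.0  # exp overflow guard; hazards this large mean instant failure


@dataclass
class HazardBatch:
    """K causes x N batch elements.

    shapes, scales : (K, N) Weibull baseline parameters
    expo           : (K, N, C) polynomial coefficients of P_k(t), lowest first
    """

    shapes: np.ndarray
    scales: np.ndarray
    expo: np.ndarray

    def __post_init__(self) -> None:
        self.shapes = np.atleast_2d(np.asarray(self.shapes, dtype=float))
        self.scales = np.atleast_2d(np.asarray(self.scales, dtype=float))
        self.expo = np.asarray(self.expo, dtype=float)
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("Weibull shape and scale must be positive")

    @property
    def n_causes(self) -> int:
        return self.expo.shape[0]

    @property
    def n(self) -> int:
        return self.expo.shape[1]


def log_hazards_at(hb: HazardBatch, t: np.ndarray) -> np.ndarray:
    """log h_k at times t.

    t may be shape (M,) (times shared across the batch), (N, M) (per-element
    times) or (K, N, M).  Result has shape (K, N, M).  All times must be > 0.
    """
    tb = np.asarray(t, dtype=float)
    if tb.ndim == 1:
        tb = tb[None, None, :]
    elif tb.ndim == 2:
        tb = tb[None, :, :]
    a = hb.shapes[..., None]
    s = hb.scales[..., None]
    base = np.log(a) - a * np.log(s) + (a - 1.0) * np.log(tb)
    return base + _poly_at(hb.expo, tb)


def _poly_at(expo: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """Horner-evaluate (K, N, C) polynomials at times tb (K|1, N|1, M)."""
    K, N, C = expo.shape
    out = np.zeros(np.broadcast_shapes((K, N, 1), tb.shape))
    for c in range(C - 1, -1, -1):
        out = out * tb + expo[:, :, c][:, :, None]
    return out


def hazards_at(hb: HazardBatch, t: np.ndarray) -> np.ndarray:
    """h_k(t), shape (K, N, M)."""
    return np.exp(np.clip(log_hazards_at(hb, t), None, _EXP_CLIP))


def total_hazard_at(hb: HazardBatch, t: np.ndarray) -> np.ndarray:
    return hazards_at(hb, t).sum(axis=0)


def _first_panel_weibull(hb: HazardBatch, b1: float, n_nodes: int) -> np.ndarray:
    """Integral of h_k over [0, b1] by Gauss-Jacobi with weight t^(shape-1),
    which absorbs the Weibull baseline's algebraic behaviour at zero.

    Requires the shape of each cause to be constant across the batch;
    returns (K, N).
    """
    from scipy.special import roots_jacobi
    K, N = hb.n_causes, hb.n
    out = np.zeros((K, N))
    for k in range(K):
        a = float(hb.shapes[k, 0])
        x, w = roots_jacobi(n_nodes, 0.0, a - 1.0)
        t = b1 * (x + 1.0) / 2.0  # (n,)
        P = _poly_at(hb.expo[k:k + 1], t[None, None, :])[0]  # (N, n)
        pref = hb.shapes[k] * hb.scales[k] ** (-hb.shapes[k]) * (b1 / 2.0) ** a
        out[k] = pref * (np.exp(np.clip(P, None, _EXP_CLIP)) @ w)
    return out


def cumhaz_at_boundaries(hb: HazardBatch, bounds: np.ndarray,
                         n_nodes: int) -> np.ndarray:
    """Per-cause cumulative hazard from bounds[0] at every boundary.

    Returns (K, N, B) with [..., 0] == 0.
    """
    tt, ww = panel_nodes(bounds, n_nodes)  # (P, n)
    h = hazards_at(hb, tt.ravel()).reshape(hb.n_causes, hb.n, *tt.shape)
    panel_ints = (h * ww[None, None]).sum(axis=-1)  # (K, N, P)
    if bounds[0] == 0.0 and np.all(np.ptp(hb.shapes, axis=1) == 0):
        panel_ints[..., 0] = _first_panel_weibull(hb, float(bounds[1]), n_nodes)
    out = np.zeros((hb.n_causes, hb.n, len(bounds)))
    np.cumsum(panel_ints, axis=-1, out=out[..., 1:])
    return out


def cumhaz_segment(hb: HazardBatch, a, b, n_nodes: int) -> np.ndarray:
    """Per-cause integral of h_k over per-element intervals [a, b].

    a, b broadcastable to (N,).  Returns (K, N).  Intervals may be empty
    (a == b) but not reversed.
    """
    N = hb.n
    a = np.broadcast_to(np.asarray(a, dtype=float), (N,))
    b = np.broadcast_to(np.asarray(b, dtype=float), (N,))
    tt, ww = interval_nodes(a, b, n_nodes)  # (N, n)
    h = hazards_at(hb, tt)  # (K, N, n)
    return (h * ww[None]).sum(axis=-1)


def invert_total_cumhaz(hb: HazardBatch, targets: np.ndarray, t_max: float,
                        rule: QuadratureRule, tol: float = 1e-6,
                        t_min: float = 1e-6) -> np.ndarray:
    """Solve H_tot(T) = target for each batch element by bracketed bisection.

    Returns T of shape (N,), with np.inf where H_tot(t_max) < target.
    """
    targets = np.asarray(targets, dtype=float)
    bounds = panel_boundaries(t_min, t_max, rule.panel_width)
    # hazard mass on [0, t_min]; Gauss nodes are interior so shape<1
    # (unbounded-at-zero) baselines stay finite here
    head = cumhaz_segment(hb, 0.0, t_min, rule.n_nodes).sum(axis=0)
    Hb = cumhaz_at_boundaries(hb, bounds, rule.n_nodes).sum(axis=0) + head[:, None]
    T = np.full(hb.n, np.inf)
    active = targets <= Hb[:, -1]
    if not np.any(active):
        return T
    idx = np.sum(Hb < targets[:, None], axis=1)  # first boundary index with H >= target
    idx = np.clip(idx, 1, len(bounds) - 1)
    lo = bounds[idx - 1].astype(float)
    hi = bounds[idx].astype(float)
    H_lo = np.take_along_axis(Hb, (idx - 1)[:, None], axis=1)[:, 0]
    for _ in range(64):
        if np.all((hi - lo)[active] <= tol):
            break
        mid = 0.5 * (lo + hi)
        Hm = H_lo + cumhaz_segment(hb, lo, mid, rule.n_nodes).sum(axis=0)
        go_right = Hm < targets
        lo = np.where(go_right & active, mid, lo)
        H_lo = np.where(go_right & active, Hm, H_lo)
        hi = np.where(~go_right & active, mid, hi)
    T[active] = (0.5 * (lo + hi))[active]
    return T


def conditional_cif_curve(hb: HazardBatch, cause_idx: int, t0: float,
                          s_grid: np.ndarray, n_nodes: int = 8
                          ) -> tuple[np.ndarray, dict]:
    """pi(t0, s) = int_t0^s h_k(u) exp(-(H(u) - H(t0))) du for each draw.

    ``s_grid`` (strictly increasing, all > t0) doubles as the panel grid, so
    values are nondecreasing along the grid draw by draw (the integrand is
    nonnegative and each grid value is a cumulative panel sum).

    Returns (pi, cache): pi of shape (N, S); cache supports
    :func:`conditional_cif_extend` for arbitrary s inside the grid range.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or np.any(np.diff(s_grid) <= 0) or s_grid[0] <= t0:
        raise ValueError("s_grid must be strictly increasing and > t0")
    bounds = np.concatenate([[t0], s_grid])  # (P+1,)
    P = len(bounds) - 1
    # survival increments over whole panels (inner rule)
    tt_full, ww_full = panel_nodes(bounds, n_nodes)  # (P, n)
    h_tot_full = total_hazard_at(hb, tt_full.ravel()).reshape(hb.n, P, n_nodes)
    panel_H = (h_tot_full * ww_full[None]).sum(axis=-1)  # (N, P)
    G_bounds = np.concatenate(
        [np.zeros((hb.n, 1)), np.cumsum(panel_H, axis=-1)], axis=1)  # (N, P+1)
    # outer nodes per panel and inner partial integrals G(a_p -> u_pj)
    u, wu = panel_nodes(bounds, n_nodes)  # (P, n) outer nodes
    a_rep = np.broadcast_to(bounds[:-1, None], u.shape)
    tin, win = interval_nodes(a_rep, u, n_nodes)  # (P, n, n)
    h_tot_in = total_hazard_at(hb, tin.reshape(1, -1)[0]).reshape(hb.n, P, n_nodes, n_nodes)
    G_u = G_bounds[:, :-1, None] + (h_tot_in * win[None]).sum(axis=-1)  # (N, P, n)
    h_k_u = hazards_at(hb, u.ravel()).reshape(hb.n_causes, hb.n, P, n_nodes)[cause_idx]
    contrib = (h_k_u * np.exp(-G_u) * wu[None]).sum(axis=-1)  # (N, P)
    pi = np.cumsum(contrib, axis=-1)  # (N, S)
    cache = {"bounds": bounds, "G_bounds": G_bounds,
             "pi_bounds": np.concatenate([np.zeros((hb.n, 1)), pi], axis=1),
             "hb": hb, "cause_idx": cause_idx, "n_nodes": n_nodes}
    return pi, cache


def conditional_cif_extend(cache: dict, s: float) -> np.ndarray:
    """Per-draw pi(t0, s) for arbitrary s within the cached grid range."""
    bounds = cache["bounds"]
    hb: HazardBatch = cache["hb"]
    n_nodes = cache["n_nodes"]
    if s <= bounds[0]:
        return np.zeros(hb.n)
    if s > bounds[-1] + 1e-12:
        raise ValueError("s beyond cached curve range")
    p = int(np.searchsorted(bounds, s, side="right") - 1)
    p = min(p, len(bounds) - 2)
    a = bounds[p]
    if s - a <= 1e-14:
        return cache["pi_bounds"][:, p].copy()
    u, wu = interval_nodes(a, s, n_nodes)  # (n,)
    tin, win = interval_nodes(np.full(n_nodes, a), u, n_nodes)  # (n, n)
    h_tot_in = total_hazard_at(hb, tin.ravel()).reshape(hb.n, n_nodes, n_nodes)
    G_u = cache["G_bounds"][:, p, None] + (h_tot_in * win[None]).sum(axis=-1)
    h_k_u = hazards_at(hb, u)[cache["cause_idx"]]  # (N, n)
    return cache["pi_bounds"][:, p] + (h_k_u * np.exp(-G_u) * wu[None]).sum(axis=-1)
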