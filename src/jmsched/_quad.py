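"""Fixed-panel Gauss-Legendre quadrature helpers.

All hazard integrals in the package use composite Gauss-Legendre rules on
fixed panels so that node placement is deterministic and results are exactly
reproducible across calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=32)
def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of the n-point Gauss-Legendre rule on [-1, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


@dataclass(frozen=True)
class QuadratureRule:
    """Composite quadrature: panels of at most ``panel_width`` years,
    ``n_nodes`` Gauss-Legendre nodes per panel."""

    panel_width: float = 0.5
    n_nodes: int = 15

    def __post_init__(self) -> None:
        if self.panel_width <= 0 or self.n_nodes < 1:
            raise ValueError("panel_width must be > 0 and n_nodes >= 1")


def panel_boundaries(a: float, b: float, width: float) -> np.ndarray:
    """Equispaced boundaries dividing [a, b] into panels of width <= ``width``."""
    if b < a:
        raise ValueError(f"empty interval [{a}, {b}]")
    if b == a:
        return np.array([a, b])
    n = max(1, int(np.ceil((b - a) / width - 1e-12)))
    return np.linspace(a, b, n + 1)


def panel_nodes(bounds: np.ndarray, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for each panel.

    Returns arrays of shape (n_panels, n_nodes); integrating f over panel p is
    ``sum(f(times[p]) * weights[p])``.
    """
    x, w = gauss_legendre(n_nodes)
    a = bounds[:-1, None]
    h = (np.diff(bounds) / 2.0)[:, None]
    return a + h * (x[None, :] + 1.0), h * np.broadcast_to(w, (len(bounds) - 1, n_nodes))


def interval_nodes(a, b, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on intervals [a, b] of any broadcastable
    shape; appends a trailing axis of length ``n_nodes``."""
    x, w = gauss_legendre(n_nodes)
    a = np.asarray(a, dtype=float)[..., None]
    h = (np.asarray(b, dtype=float)[..., None] - a) / 2.0
    return a + h * (x + 1.0), h * w
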