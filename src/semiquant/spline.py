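"""Monotone piecewise-linear spline measurement mappings.

The mapping is parameterized by knot bases c_1 < ... < c_n on a uniform grid
anchored at the origin (c_0 = 0) and nonnegative height increments xi_j, so
the knot heights are the cumulative sums of xi and the mapping is monotone
nondecreasing by construction:

    s(x) = (x - c_{j-1})/dc * xi_j + sum_{l<j} xi_l   for c_{j-1} <= x <= c_j,

with the first branch a line through the origin and constant extrapolation at
the total height beyond the last knot.  The mapping is linear in xi, which
makes the inner estimation problem a convex nonnegativity-constrained least
squares problem (see :mod:`semiquant.inner`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplineMapping",
    "RegularizationConfig",
    "make_knot_grid",
    "eval_spline",
    "spline_basis_matrix",
    "spline_derivative",
    "regularization_penalty",
]


@dataclass(frozen=True)
class RegularizationConfig:
    """Strength of the linearity-promoting penalty on the spline increments."""

    strength: float = 1e-2
    enabled: bool = True

    def __post_init__(self):
        if self.strength < 0:
            raise ValueError("regularization strength must be nonnegative")

    @property
    def effective_strength(self) -> float:
        return self.strength if self.enabled else 0.0


class SplineMapping:
    """A monotone piecewise-linear mapping with fixed knot bases.

    Parameters
    ----------
    knots : array
        Strictly increasing knot bases with (near-)uniform spacing; the grid
        is implicitly anchored at the origin.
    increments : array
        Nonnegative height increments xi, one per knot.
    """

    def __init__(self, knots, increments):
        c = np.asarray(knots, dtype=float)
        xi = np.asarray(increments, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("knots must be a 1-d array with at least one entry")
        if xi.shape != c.shape:
            raise ValueError("increments must align with knots")
        edges = np.diff(np.concatenate([[0.0], c]))
        if np.any(edges <= 0):
            raise ValueError("knots must be strictly increasing and positive")
        if c.size > 1 and not np.allclose(edges, edges[0], rtol=1e-8, atol=0):
            raise ValueError("knot bases must be uniformly spaced")
        if np.any(xi < -1e-14):
            raise ValueError("increments must be nonnegative")
        self.knots = c
        self.increments = np.maximum(xi, 0.0)
        self._edges = np.concatenate([[0.0], c])      # c_0 .. c_n
        self._widths = edges
        self._heights = np.concatenate([[0.0], np.cumsum(self.increments)])

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def spacing(self) -> float:
        return float(self._widths[-1])

    @property
    def knot_heights(self) -> np.ndarray:
        """Heights at the knot bases (cumulative increments)."""
        return self._heights[1:].copy()

    @property
    def total_height(self) -> float:
        return float(self._heights[-1])

    def __call__(self, x):
        return eval_spline(self, x)

    def derivative(self, x):
        return spline_derivative(self, x)

    def basis_matrix(self, x) -> np.ndarray:
        return spline_basis_matrix(self, x)

    def with_increments(self, increments) -> "SplineMapping":
        return SplineMapping(self.knots, increments)

    def __repr__(self):
        return f"SplineMapping(n_knots={self.n_knots}, spacing={self.spacing:.4g})"


def make_knot_grid(sim_values, n_knots: int, margin: float = 0.3) -> np.ndarray:
    """Uniform origin-anchored knot grid covering the simulated range.

    The grid spans [0, (1+margin)*max(sim_values)] with c_j = j*dc, so the
    first branch of the spline coincides with the generic branch and the
    mapping passes through the origin.
    """
    v = np.asarray(sim_values, dtype=float)
    if n_knots < 2:
        raise ValueError("need at least two knots")
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("simulated values must be nonempty and finite")
    vmax = float(np.max(v))
    if vmax <= 0:
        raise ValueError(
            "maximum simulated value is nonpositive; apply an observable "
            "transformation so the mapped quantity is positive"
        )
    dc = (1.0 + margin) * vmax / n_knots
    return dc * np.arange(1, n_knots + 1)


def _interval_index(m: SplineMapping, x: np.ndarray, side: str) -> np.ndarray:
    # 0-based interval index: interval j covers [c_j, c_{j+1}] of the extended grid
    return np.clip(np.searchsorted(m.knots, x, side=side), 0, m.n_knots - 1)


def eval_spline(m: SplineMapping, x):
    """Evaluate the mapping at scalar or vector ``x`` (continuous everywhere)."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    j = _interval_index(m, xv, side="left")
    frac = (xv - m._edges[j]) / m._widths[j]
    out = frac * m.increments[j] + m._heights[j]
    out = np.where(xv > m.knots[-1], m.total_height, out)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def spline_basis_matrix(m: SplineMapping, x) -> np.ndarray:
    """Matrix B with B[k, j] = ds(x_k)/dxi_j, so s(x_k) = (B @ xi)_k exactly."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    n = m.n_knots
    j = _interval_index(m, xv, side="left")
    frac = (xv - m._edges[j]) / m._widths[j]
    frac = np.where(xv > m.knots[-1], 1.0, frac)
    cols = np.arange(n)[None, :]
    b = np.where(cols < j[:, None], 1.0, 0.0)
    b[np.arange(xv.size), j] = frac
    return b


def spline_derivative(m: SplineMapping, x):
    """Local slope xi_j / dc; right-interval slope at interior knots, 0 beyond."""
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    j = _interval_index(m, xv, side="right")
    out = m.increments[j] / m._widths[j]
    out = np.where(xv >= m.knots[-1], 0.0, out)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def regularization_penalty(increments, cfg: RegularizationConfig):
    """Penalty (lam/2) * sum_j (xi_j - mean(xi))^2 and its analytic gradient.

    Zero exactly when all increments are equal, i.e. when the spline is
    globally linear on [0, c_n]; quadratic and convex in xi.
    """
    xi = np.asarray(increments, dtype=float)
    lam = cfg.effective_strength
    if lam == 0.0:
        return 0.0, np.zeros_like(xi)
    centered = xi - xi.mean()
    return 0.5 * lam * float(centered @ centered), lam * centered
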