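"""Per-observable inner problems of the hierarchical likelihood split.

Each observable contributes an additively separable term J_i to the negative
log-likelihood, depending only on its own observable parameters psi_i:

* quantitative observables carry no mapping parameters (identity mapping);
  only a single noise SD may be estimated;
* relative observables use an affine mapping g(y) = a*y + b with the
  ordinary-least-squares closed form for (a, b) and the MLE for sigma;
* nonlinear-monotone observables use the spline mapping, whose inner problem

      min_{xi >= 0}  (1/(2 sigma^2)) ||z - B xi||^2 + (lam/2) ||xi - mean(xi)||^2

  is a convex quadratic program solved by nonnegative least squares on a
  Tikhonov-augmented system.

All noise lives on the measurement scale (after the mapping).  With a single
estimated sigma per observable, the MLE sigma is the RMS residual; the
sigma-lambda coupling under regularization is resolved by a short fixed-point
iteration that preserves per-step convexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .spline import (
    RegularizationConfig,
    SplineMapping,
    make_knot_grid,
    regularization_penalty,
    spline_basis_matrix,
    spline_derivative,
)

__all__ = [
    "SIGMA_FLOOR",
    "ObservableConfig",
    "MeasurementSet",
    "InnerSolution",
    "gaussian_nll",
    "solve_quantitative",
    "solve_relative",
    "solve_spline_inner",
    "solve_inner_all",
]

#: lower bound on any estimated noise SD, keeping the log-likelihood finite on
#: perfectly fit data (units of the measurement)
SIGMA_FLOOR = 1e-10

MAPPING_CLASSES = ("quantitative", "relative", "nonlinear_monotone")
NOISE_MODES = ("known", "estimate_single")


@dataclass(frozen=True)
class ObservableConfig:
    """Mapping class, noise model and spline settings for one observable."""

    observable_id: str
    mapping_class: str = "quantitative"
    noise_mode: str = "estimate_single"
    known_sigma: float | None = None
    n_knots: int = 8
    margin: float = 0.3
    regularization: RegularizationConfig = field(default_factory=RegularizationConfig)

    def __post_init__(self):
        if self.mapping_class not in MAPPING_CLASSES:
            raise ValueError(f"unknown mapping class {self.mapping_class!r}")
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.noise_mode == "known" and (self.known_sigma is None or self.known_sigma <= 0):
            raise ValueError("known noise mode requires a positive known_sigma")


class MeasurementSet:
    """Measurements grouped per observable, ordered by time within each.

    Stores, per observable id, the measurement times, values, and (optionally)
    per-point known noise SDs from the measurement table.
    """

    def __init__(self, records: Iterable[tuple[str, float, float]] | None = None):
        self._times: dict[str, list[float]] = {}
        self._values: dict[str, list[float]] = {}
        self._sigmas: dict[str, list[float | None]] = {}
        if records:
            for rec in records:
                self.add(*rec)

    def add(self, observable_id: str, time: float, value: float, sigma: float | None = None):
        if not np.isfinite(value) or not np.isfinite(time):
            raise ValueError(f"non-finite measurement for {observable_id!r} at t={time}")
        self._times.setdefault(observable_id, []).append(float(time))
        self._values.setdefault(observable_id, []).append(float(value))
        self._sigmas.setdefault(observable_id, []).append(
            None if sigma is None or (isinstance(sigma, float) and np.isnan(sigma)) else float(sigma)
        )

    @property
    def observable_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._times))

    def __len__(self) -> int:
        return sum(len(v) for v in self._values.values())

    def times(self, observable_id: str) -> np.ndarray:
        order = np.argsort(self._times[observable_id], kind="stable")
        return np.asarray(self._times[observable_id], float)[order]

    def values(self, observable_id: str) -> np.ndarray:
        order = np.argsort(self._times[observable_id], kind="stable")
        return np.asarray(self._values[observable_id], float)[order]

    def sigmas(self, observable_id: str) -> np.ndarray | None:
        """Known per-point noise SDs, or None if not given for this observable."""
        raw = self._sigmas[observable_id]
        if all(s is None for s in raw):
            return None
        if any(s is None for s in raw):
            raise ValueError(f"observable {observable_id!r} mixes known and unknown noise values")
        order = np.argsort(self._times[observable_id], kind="stable")
        return np.asarray(raw, float)[order]

    def all_times(self) -> np.ndarray:
        """Sorted union of measurement times across observables."""
        ts = sorted({t for times in self._times.values() for t in times})
        return np.asarray(ts, float)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for oid in self.observable_ids:
            sig = self._sigmas[oid]
            order = np.argsort(self._times[oid], kind="stable")
            for k in order:
                rows.append({
                    "observableId": oid,
                    "time": self._times[oid][k],
                    "measurement": self._values[oid][k],
                    "noiseValue": np.nan if sig[k] is None else sig[k],
                })
        df = pd.DataFrame(rows, columns=["observableId", "time", "measurement", "noiseValue"])
        if df["noiseValue"].isna().all():
            df = df.drop(columns=["noiseValue"])
        return df


@dataclass
class InnerSolution:
    """Optimal observable parameters, noise and objective for one observable."""

    observable_id: str
    mapping_class: str
    parameters: dict
    sigma: np.ndarray            # per-point noise SDs actually used in J_i
    objective: float             # J_i including any regularization term
    residuals: np.ndarray        # mapped simulation minus measurement
    mapped: np.ndarray           # g(y_ik) at the optimum
    slopes: np.ndarray           # g'(y_ik) at the optimum, for the outer gradient
    mapping: SplineMapping | None = None
    identifiable: bool = True


def gaussian_nll(residuals: np.ndarray, sigmas: np.ndarray) -> float:
    """Negative log-likelihood of independent Gaussian residuals."""
    r = np.asarray(residuals, float)
    s = np.asarray(sigmas, float)
    return float(np.sum(0.5 * np.log(2.0 * np.pi * s**2) + r**2 / (2.0 * s**2)))


def _resolve_sigma(cfg: ObservableConfig, known: np.ndarray | None, n: int) -> np.ndarray | None:
    """Per-point sigma vector if the noise is known, else None (to estimate)."""
    if known is not None:
        return np.asarray(known, float)
    if cfg.noise_mode == "known":
        return np.full(n, float(cfg.known_sigma))
    return None


def _estimated_sigma(residuals: np.ndarray) -> float:
    return max(float(np.sqrt(np.mean(residuals**2))), SIGMA_FLOOR)


def solve_quantitative(y, z, cfg: ObservableConfig, known_sigmas=None) -> InnerSolution:
    """Identity mapping; only the noise SD may be estimated."""
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    res = y - z
    sig = _resolve_sigma(cfg, known_sigmas, z.size)
    if sig is None:
        sig = np.full(z.size, _estimated_sigma(res))
    return InnerSolution(
        observable_id=cfg.observable_id, mapping_class="quantitative",
        parameters={}, sigma=sig, objective=gaussian_nll(res, sig),
        residuals=res, mapped=y.copy(), slopes=np.ones_like(y),
    )


def solve_relative(y, z, cfg: ObservableConfig, known_sigmas=None) -> InnerSolution:
    """Closed-form affine mapping g(y) = a*y + b by (weighted) least squares.

    With known per-point sigmas the closed form is the weighted OLS solution;
    with a single estimated sigma the weights drop out and sigma^2 is the mean
    squared residual (the Gaussian MLE).
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if z.size < 3:
        warnings.warn(
            f"observable {cfg.observable_id!r}: fewer than 3 points for 2 mapping "
            "parameters plus noise", stacklevel=2)
    sig = _resolve_sigma(cfg, known_sigmas, z.size)
    w = np.ones_like(z) if sig is None else 1.0 / sig**2
    wsum = w.sum()
    ybar = float(w @ y) / wsum
    zbar = float(w @ z) / wsum
    syy = float(w @ (y - ybar) ** 2)
    identifiable = syy > 1e-14 * max(1.0, ybar**2)
    if identifiable:
        a = float(w @ ((y - ybar) * (z - zbar))) / syy
        b = zbar - a * ybar
    else:
        a, b = 0.0, zbar
    mapped = a * y + b
    res = mapped - z
    if sig is None:
        sig = np.full(z.size, _estimated_sigma(res))
    return InnerSolution(
        observable_id=cfg.observable_id, mapping_class="relative",
        parameters={"scale": a, "offset": b}, sigma=sig,
        objective=gaussian_nll(res, sig), residuals=res, mapped=mapped,
        slopes=np.full_like(y, a), identifiable=identifiable,
    )


def _nnls_penalized(b_mat: np.ndarray, z: np.ndarray, weights: np.ndarray,
                    lam_eff: float) -> np.ndarray:
    """Solve min_{xi>=0} 1/2 ||W^{1/2}(B xi - z)||^2 + (lam_eff/2)||M xi||^2.

    M = I - (1/n) 11^T is the mean-centering projector, so the penalty equals
    the squared distance of xi from its own mean; stacking sqrt(lam_eff)*M
    under the weighted design reduces the problem to plain NNLS.
    """
    sw = np.sqrt(weights)
    a = b_mat * sw[:, None]
    rhs = z * sw
    if lam_eff > 0:
        n = b_mat.shape[1]
        m_proj = np.eye(n) - np.full((n, n), 1.0 / n)
        a = np.vstack([a, np.sqrt(lam_eff) * m_proj])
        rhs = np.concatenate([rhs, np.zeros(n)])
    try:
        xi, _ = nnls(a, rhs)
    except RuntimeError as err:  # pragma: no cover - nnls rarely fails
        raise RuntimeError(f"inner quadratic program did not converge: {err}") from err
    return xi


def solve_spline_inner(y, z, cfg: ObservableConfig, known_sigmas=None,
                       knots: np.ndarray | None = None,
                       max_fixed_point: int = 10, fp_tol: float = 1e-10) -> InnerSolution:
    """Convex spline inner problem: NNLS on the Tikhonov-augmented system.

    When sigma is estimated together with a nonzero penalty, the coupling is
    resolved by a fixed-point pass (solve xi at the current sigma, update
    sigma from the residuals, re-solve) which converges in a few iterations;
    for lam = 0 the optimal xi is independent of a single sigma and one solve
    suffices.
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if knots is None:
        knots = make_knot_grid(y, cfg.n_knots, cfg.margin)
    n_knots = knots.size
    if z.size < n_knots + 1:
        warnings.warn(
            f"observable {cfg.observable_id!r}: {z.size} points for {n_knots} spline "
            "increments; the inner problem may be underdetermined", stacklevel=2)
    template = SplineMapping(knots, np.zeros(n_knots))
    b_mat = spline_basis_matrix(template, y)
    lam = cfg.regularization.effective_strength
    sig = _resolve_sigma(cfg, known_sigmas, z.size)

    def objective(xi, sig_vec):
        mapped = b_mat @ xi
        res = mapped - z
        pen, _ = regularization_penalty(xi, cfg.regularization)
        return gaussian_nll(res, sig_vec), res, mapped, pen

    if sig is not None:
        xi = _nnls_penalized(b_mat, z, 1.0 / sig**2, lam)
        j_val, res, mapped, pen = objective(xi, sig)
        sig_out = sig
    else:
        sigma = 1.0
        xi = _nnls_penalized(b_mat, z, np.ones_like(z), lam * sigma**2)
        res = b_mat @ xi - z
        sigma = _estimated_sigma(res)
        j_prev = np.inf
        for _ in range(max_fixed_point if lam > 0 else 0):
            xi = _nnls_penalized(b_mat, z, np.ones_like(z), lam * sigma**2)
            res = b_mat @ xi - z
            sigma = _estimated_sigma(res)
            j_cur = gaussian_nll(res, np.full_like(z, sigma)) + \
                regularization_penalty(xi, cfg.regularization)[0]
            if abs(j_cur - j_prev) <= fp_tol * max(1.0, abs(j_cur)):
                break
            j_prev = j_cur
        sig_out = np.full(z.size, sigma)
        j_val, res, mapped, pen = objective(xi, sig_out)

    mapping = SplineMapping(knots, xi)
    return InnerSolution(
        observable_id=cfg.observable_id, mapping_class="nonlinear_monotone",
        parameters={"increments": xi.copy(), "knots": knots.copy()},
        sigma=sig_out, objective=j_val + pen, residuals=res, mapped=mapped,
        slopes=spline_derivative(mapping, y), mapping=mapping,
    )


_SOLVERS: dict[str, Callable] = {
    "quantitative": solve_quantitative,
    "relative": solve_relative,
    "nonlinear_monotone": solve_spline_inner,
}


def solve_inner_all(sim, data: MeasurementSet, configs: Sequence[ObservableConfig],
                    observable_names: Sequence[str],
                    knot_grids: Mapping[str, np.ndarray] | None = None,
                    ) -> dict[str, InnerSolution]:
    """Solve every observable's inner problem against one simulation.

    The problems are independent across observables, so the result does not
    depend on the configuration order.  Simulated values are matched to
    measurement times by position in the simulation time grid.
    """
    if not sim.success:
        raise RuntimeError("cannot solve inner problems for a failed simulation")
    cfg_by_id = {c.observable_id: c for c in configs}
    name_index = {n: i for i, n in enumerate(observable_names)}
    solutions: dict[str, InnerSolution] = {}
    for oid in data.observable_ids:
        cfg = cfg_by_id.get(oid)
        if cfg is None:
            raise KeyError(f"no observable configuration for measured observable {oid!r}")
        if oid not in name_index:
            raise KeyError(f"measured observable {oid!r} is not a model observable")
        t_idx = np.searchsorted(sim.times, data.times(oid))
        if np.any(t_idx >= sim.times.size) or not np.allclose(
                sim.times[t_idx], data.times(oid), rtol=1e-12, atol=1e-12):
            raise ValueError(f"measurement times for {oid!r} missing from the simulation grid")
        y = sim.observables[name_index[oid], t_idx]
        z = data.values(oid)
        kwargs = {"known_sigmas": data.sigmas(oid)}
        if cfg.mapping_class == "nonlinear_monotone" and knot_grids is not None:
            kwargs["knots"] = knot_grids.get(oid)
        try:
            solutions[oid] = _SOLVERS[cfg.mapping_class](y, z, cfg, **kwargs)
        except Exception as err:
            raise RuntimeError(f"inner solve failed for observable {oid!r}: {err}") from err
    return solutions
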