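"""Hierarchical negative log-likelihood and its analytic outer gradient.

The estimation problem is split hierarchically: the outer problem minimizes
J(theta, psi*(theta)) over the mechanistic parameters theta, while for each
candidate theta the observable parameters psi_i (affine scale/offset, spline
increments, noise SDs) are profiled out exactly by the per-observable inner
solvers.  Because psi*(theta) is an inner optimum, inner parameters contribute
no first-order terms (envelope result) and the outer gradient reduces to

    dJ/dtheta = sum_{i,k} (m_ik - z_ik)/sigma_i^2 * g_i'(y_ik) * dy_ik/dtheta

with m_ik the mapped simulation and g_i' the local mapping slope (1 for
quantitative, a*_i for relative, the local spline slope otherwise); the
observable sensitivities come from the forward-sensitivity simulation and are
already expressed on the (log10) optimization scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .inner import (
    InnerSolution,
    MeasurementSet,
    ObservableConfig,
    gaussian_nll,
    solve_inner_all,
)
from .models import CompiledModel, ODEModelSpec, SimulationResult, compile_model
from .spline import SplineMapping, make_knot_grid, regularization_penalty, spline_derivative

__all__ = ["ObjectiveEvaluation", "HierarchicalObjective", "JointObjective"]


@dataclass
class ObjectiveEvaluation:
    """One evaluation of the hierarchical objective at a parameter vector."""

    value: float
    gradient: np.ndarray | None
    inner: dict[str, InnerSolution] | None
    simulation: SimulationResult | None
    message: str = ""


class HierarchicalObjective:
    """J(theta, psi*(theta)) with analytic gradient for gradient-based solvers.

    Parameters
    ----------
    model : ODEModelSpec or CompiledModel
    data : MeasurementSet
    configs : observable configurations covering every measured observable
    knot_grids : optional mapping observable id -> fixed knot bases.  By
        default the knot grid of each spline observable is rebuilt from the
        current simulation at every evaluation (adaptive mode); a fixed grid
        gives a strictly smooth objective, used for gradient verification and
        for comparisons against the joint formulation.
    """

    def __init__(self, model, data: MeasurementSet, configs: Sequence[ObservableConfig],
                 knot_grids: Mapping[str, np.ndarray] | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10, method: str = "LSODA"):
        self.model: CompiledModel = model if isinstance(model, CompiledModel) else compile_model(model)
        self.spec: ODEModelSpec = self.model.spec
        self.data = data
        self.configs = tuple(configs)
        self.knot_grids = dict(knot_grids) if knot_grids is not None else None
        self.rtol, self.atol, self.method = rtol, atol, method
        measured = set(data.observable_ids)
        configured = {c.observable_id for c in self.configs}
        missing = measured - configured
        if missing:
            raise ValueError(f"no observable configuration for: {sorted(missing)}")
        unknown = measured - set(self.spec.observable_names)
        if unknown:
            raise ValueError(f"measured observables not in the model: {sorted(unknown)}")
        self.times = data.all_times()
        # bookkeeping for optimizers / efficiency comparisons
        self.n_evaluations = 0
        self.trace: list[tuple[int, float]] = []

    # ------------------------------------------------------------------
    def reset_counters(self):
        self.n_evaluations = 0
        self.trace = []

    def freeze_grids(self, theta) -> dict[str, np.ndarray]:
        """Knot grids computed from the simulation at ``theta`` (fixed-grid mode)."""
        sim = self.model.simulate(theta, self.times, rtol=self.rtol, atol=self.atol,
                                  method=self.method)
        if not sim.success:
            raise RuntimeError("cannot freeze knot grids: simulation failed")
        grids = {}
        name_index = {n: i for i, n in enumerate(self.spec.observable_names)}
        for cfg in self.configs:
            if cfg.mapping_class == "nonlinear_monotone":
                y = sim.observables[name_index[cfg.observable_id]]
                grids[cfg.observable_id] = make_knot_grid(y, cfg.n_knots, cfg.margin)
        return grids

    def with_grids(self, knot_grids: Mapping[str, np.ndarray]) -> "HierarchicalObjective":
        return HierarchicalObjective(self.model, self.data, self.configs,
                                     knot_grids=knot_grids, rtol=self.rtol,
                                     atol=self.atol, method=self.method)

    # ------------------------------------------------------------------
    def evaluate(self, theta, with_gradient: bool = False) -> ObjectiveEvaluation:
        """Simulate, solve all inner problems, and assemble J (and its gradient)."""
        theta = np.asarray(theta, float)
        sim = self.model.simulate(theta, self.times, with_sensitivities=with_gradient,
                                  rtol=self.rtol, atol=self.atol, method=self.method)
        self.n_evaluations += 1
        if not sim.success:
            self.trace.append((self.n_evaluations, np.inf))
            return ObjectiveEvaluation(np.inf, None, None, sim,
                                       message=f"simulation failed: {sim.message}")
        try:
            inner = solve_inner_all(sim, self.data, self.configs,
                                    self.spec.observable_names, knot_grids=self.knot_grids)
        except (RuntimeError, ValueError, KeyError) as err:
            self.trace.append((self.n_evaluations, np.inf))
            return ObjectiveEvaluation(np.inf, None, None, sim, message=str(err))
        value = float(sum(sol.objective for sol in inner.values()))
        gradient = None
        if with_gradient:
            gradient = np.zeros(self.spec.n_parameters)
            name_index = {n: i for i, n in enumerate(self.spec.observable_names)}
            for oid, sol in inner.items():
                t_idx = np.searchsorted(self.times, self.data.times(oid))
                sens = sim.observable_sensitivities[name_index[oid], t_idx, :]
                w = sol.residuals / sol.sigma**2 * sol.slopes
                gradient += w @ sens
            if not np.all(np.isfinite(gradient)):
                return ObjectiveEvaluation(np.inf, None, inner, sim,
                                           message="non-finite gradient")
        self.trace.append((self.n_evaluations, value))
        return ObjectiveEvaluation(value, gradient, inner, sim)

    # optimizer-facing contract -----------------------------------------
    def __call__(self, theta) -> float:
        return self.evaluate(theta).value

    def value_and_grad(self, theta) -> tuple[float, np.ndarray]:
        ev = self.evaluate(theta, with_gradient=True)
        if ev.gradient is None:
            return ev.value, np.zeros(self.spec.n_parameters)
        return ev.value, ev.gradient


class JointObjective:
    """The same likelihood optimized jointly in (theta, psi).

    The non-hierarchical baseline: mechanistic parameters and observable
    parameters (affine scale/offset, spline increments) live in one stacked
    vector.  Noise SDs are profiled analytically in both formulations so the
    two objectives are directly comparable; at psi = psi*(theta) the joint
    value equals the hierarchical value exactly.  Spline knot grids must be
    fixed up front (the stacked xi refer to a definite grid).
    """

    def __init__(self, model, data: MeasurementSet, configs: Sequence[ObservableConfig],
                 knot_grids: Mapping[str, np.ndarray],
                 rtol: float = 1e-8, atol: float = 1e-10, method: str = "LSODA"):
        self.model = model if isinstance(model, CompiledModel) else compile_model(model)
        self.spec = self.model.spec
        self.data = data
        self.configs = {c.observable_id: c for c in configs}
        self.knot_grids = dict(knot_grids)
        self.rtol, self.atol, self.method = rtol, atol, method
        self.times = data.all_times()
        self.n_evaluations = 0
        # stacked layout: theta, then psi blocks in sorted observable order
        self._blocks: list[tuple[str, str, int]] = []
        for oid in data.observable_ids:
            cfg = self.configs[oid]
            if cfg.mapping_class == "relative":
                self._blocks.append((oid, "relative", 2))
            elif cfg.mapping_class == "nonlinear_monotone":
                if oid not in self.knot_grids:
                    raise ValueError(f"joint objective needs a fixed knot grid for {oid!r}")
                self._blocks.append((oid, "spline", self.knot_grids[oid].size))

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters + sum(n for _, _, n in self._blocks)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        bnds: list[tuple[float | None, float | None]] = list(
            zip(self.spec.lower_bounds, self.spec.upper_bounds))
        for _, kind, n in self._blocks:
            bnds += [(None, None)] * 2 if kind == "relative" else [(0.0, None)] * n
        return bnds

    def initial_psi(self) -> np.ndarray:
        """Neutral observable-parameter start: unit affine, identity-ramp spline."""
        parts = []
        for oid, kind, n in self._blocks:
            if kind == "relative":
                parts.append(np.array([1.0, 0.0]))
            else:
                grid = self.knot_grids[oid]
                parts.append(np.full(n, grid[0]))
        return np.concatenate(parts) if parts else np.zeros(0)

    def pack(self, theta, psi_blocks: Mapping[str, np.ndarray]) -> np.ndarray:
        parts = [np.asarray(theta, float)]
        for oid, _, _ in self._blocks:
            parts.append(np.asarray(psi_blocks[oid], float))
        return np.concatenate(parts)

    def unpack(self, v: np.ndarray):
        nth = self.spec.n_parameters
        theta = v[:nth]
        psi, pos = {}, nth
        for oid, _, n in self._blocks:
            psi[oid] = v[pos:pos + n]
            pos += n
        return theta, psi

    def value_and_grad(self, v) -> tuple[float, np.ndarray]:
        v = np.asarray(v, float)
        theta, psi = self.unpack(v)
        sim = self.model.simulate(theta, self.times, with_sensitivities=True,
                                  rtol=self.rtol, atol=self.atol, method=self.method)
        self.n_evaluations += 1
        if not sim.success:
            return np.inf, np.zeros(v.size)
        name_index = {n: i for i, n in enumerate(self.spec.observable_names)}
        value = 0.0
        grad = np.zeros(v.size)
        nth = self.spec.n_parameters
        pos = nth
        for oid in self.data.observable_ids:
            cfg = self.configs[oid]
            t_idx = np.searchsorted(self.times, self.data.times(oid))
            y = sim.observables[name_index[oid], t_idx]
            sens = sim.observable_sensitivities[name_index[oid], t_idx, :]
            z = self.data.values(oid)
            known = self.data.sigmas(oid)
            if known is None and cfg.noise_mode == "known":
                known = np.full(z.size, float(cfg.known_sigma))

            if cfg.mapping_class == "quantitative":
                mapped, slopes = y, np.ones_like(y)
                dpsi = None
            elif cfg.mapping_class == "relative":
                a, b = psi[oid]
                mapped, slopes = a * y + b, np.full_like(y, a)
            else:
                mapping = SplineMapping(self.knot_grids[oid], psi[oid])
                b_mat = mapping.basis_matrix(y)
                mapped = b_mat @ psi[oid]
                slopes = spline_derivative(mapping, y)
            res = mapped - z
            if known is not None:
                sig = known
            else:
                sig = np.full(z.size, max(float(np.sqrt(np.mean(res**2))), 1e-10))
            value += gaussian_nll(res, sig)
            w = res / sig**2
            grad[:nth] += (w * slopes) @ sens
            if cfg.mapping_class == "relative":
                grad[pos] = float(w @ y)
                grad[pos + 1] = float(np.sum(w))
                pos += 2
            elif cfg.mapping_class == "nonlinear_monotone":
                pen, pen_grad = regularization_penalty(psi[oid], cfg.regularization)
                value += pen
                grad[pos:pos + psi[oid].size] = b_mat.T @ w + pen_grad
                pos += psi[oid].size
        return float(value), grad

    def __call__(self, v) -> float:
        return self.value_and_grad(v)[0]
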