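"""Declarative ODE models, simulation, and forward sensitivities.

A model is a small symbolic dynamical system

    dx/dt = f(x, theta, t),   x(t0) = x0(theta),   y = h(x, theta)

with the mechanistic parameters ``theta`` estimated on a per-parameter scale
(log10 for kinetic constants by default).  Compilation differentiates the
right-hand side, the initial condition and the observation map symbolically
once; simulation then integrates the augmented forward-sensitivity system

    dS/dt = (df/dx) S + df/dtheta,   S(t0) = dx0/dtheta

and chains the state sensitivities through the observation map, so every
simulation can return both the observables y_i(t_k) and their parameter
sensitivities dy/dtheta on the optimization scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "ModelSpecificationError",
    "ODEModelSpec",
    "SimulationResult",
    "CompiledModel",
    "compile_model",
    "simulate",
]

LN10 = float(np.log(10.0))


class ModelSpecificationError(ValueError):
    """Raised when a model definition is internally inconsistent."""


class _SimulationDiverged(RuntimeError):
    """Internal: aborts the integrator on unbounded or non-finite states."""


#: state magnitude beyond which an integration is declared divergent
STATE_OVERFLOW = 1e12


@dataclass(frozen=True)
class ODEModelSpec:
    """Symbolic definition of an ODE model with observables and bounds.

    Expressions are strings over the state names, parameter names, constants
    and the time symbol ``t``.  Bounds are given on the declared estimation
    scale (``log10`` or ``lin``) per parameter.
    """

    name: str
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    rhs_exprs: tuple[str, ...]
    init_exprs: tuple[str, ...]
    observable_names: tuple[str, ...]
    observable_exprs: tuple[str, ...]
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]
    scales: tuple[str, ...]
    constants: tuple[tuple[str, float], ...] = ()
    t0: float = 0.0

    def __post_init__(self):
        nx, nth = len(self.state_names), len(self.parameter_names)
        if not (len(self.rhs_exprs) == nx == len(self.init_exprs)):
            raise ModelSpecificationError(
                "states, odes and initial conditions must align "
                f"(got {nx} states, {len(self.rhs_exprs)} odes, "
                f"{len(self.init_exprs)} initials)"
            )
        if len(self.observable_exprs) != len(self.observable_names):
            raise ModelSpecificationError("observable names/expressions must align")
        if not (len(self.lower_bounds) == len(self.upper_bounds) == len(self.scales) == nth):
            raise ModelSpecificationError("bounds and scales must cover every parameter")
        for lo, up, name in zip(self.lower_bounds, self.upper_bounds, self.parameter_names):
            if not (np.isfinite(lo) and np.isfinite(up) and lo < up):
                raise ModelSpecificationError(f"bounds for {name!r} must be finite with lower < upper")
        for s in self.scales:
            if s not in ("log10", "lin"):
                raise ModelSpecificationError(f"unknown parameter scale {s!r}")

    # -- scale handling ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_observables(self) -> int:
        return len(self.observable_names)

    def to_linear(self, theta_scaled: np.ndarray) -> np.ndarray:
        """Map a parameter vector from the estimation scale to the model scale."""
        th = np.asarray(theta_scaled, dtype=float)
        out = th.copy()
        for j, s in enumerate(self.scales):
            if s == "log10":
                out[j] = 10.0 ** th[j]
        return out

    def to_scaled(self, theta_linear: np.ndarray) -> np.ndarray:
        th = np.asarray(theta_linear, dtype=float)
        out = th.copy()
        for j, s in enumerate(self.scales):
            if s == "log10":
                out[j] = np.log10(th[j])
        return out

    def sample_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lower_bounds, float), np.asarray(self.upper_bounds, float)


@dataclass
class SimulationResult:
    """Trajectories of the observables and (optionally) their sensitivities."""

    times: np.ndarray                        # (nt,)
    states: np.ndarray                       # (nx, nt)
    observables: np.ndarray                  # (ny, nt)
    observable_sensitivities: np.ndarray | None  # (ny, nt, ntheta), optimization scale
    success: bool
    message: str = ""


def _symbolize(spec: ODEModelSpec):
    t = sp.Symbol("t")
    xs = [sp.Symbol(n) for n in spec.state_names]
    ps = [sp.Symbol(n) for n in spec.parameter_names]
    ns = {s.name: s for s in xs + ps}
    ns["t"] = t
    consts = {sp.Symbol(k): sp.Float(v) for k, v in spec.constants}

    def parse(expr: str, where: str) -> sp.Expr:
        try:
            e = sp.sympify(expr, locals=dict(ns))
        except (sp.SympifyError, SyntaxError, TypeError) as err:
            raise ModelSpecificationError(f"cannot parse {where}: {expr!r} ({err})") from err
        e = e.subs(consts)
        extra = e.free_symbols - set(xs) - set(ps) - {t}
        if extra:
            names = ", ".join(sorted(s.name for s in extra))
            raise ModelSpecificationError(f"unknown symbol(s) {names} in {where}: {expr!r}")
        return e

    f = sp.Matrix([parse(e, f"ode for {n}") for e, n in zip(spec.rhs_exprs, spec.state_names)])
    x0 = sp.Matrix([parse(e, f"initial for {n}") for e, n in zip(spec.init_exprs, spec.state_names)])
    for e, n in zip(x0, spec.state_names):
        if set(e.free_symbols) & set(xs):
            raise ModelSpecificationError(f"initial condition for {n} may not reference states")
    h = sp.Matrix([parse(e, f"observable {n}") for e, n in zip(spec.observable_exprs, spec.observable_names)])
    return t, xs, ps, f, x0, h


class CompiledModel:
    """Numerical evaluators for a model, built once by symbolic differentiation.

    Exposes ``f``, ``df/dx``, ``df/dtheta``, ``h``, ``dh/dx``, ``dh/dtheta``,
    ``x0`` and ``dx0/dtheta`` as numpy callables plus a :meth:`simulate` driver.
    """

    def __init__(self, spec: ODEModelSpec):
        self.spec = spec
        t, xs, ps, f, x0, h = _symbolize(spec)
        args = (t, xs, ps)
        mods = ["numpy"]
        self._f = sp.lambdify(args, list(f), modules=mods)
        self._fx = sp.lambdify(args, f.jacobian(xs), modules=mods)
        self._fp = sp.lambdify(args, f.jacobian(ps) if ps else sp.zeros(len(xs), 0), modules=mods)
        self._h = sp.lambdify(args, list(h), modules=mods)
        self._hx = sp.lambdify(args, h.jacobian(xs) if len(h) else sp.zeros(0, len(xs)), modules=mods)
        self._hp = sp.lambdify(args, h.jacobian(ps) if (len(h) and ps) else sp.zeros(len(h), len(ps)), modules=mods)
        self._x0 = sp.lambdify((ps,), list(x0), modules=mods)
        self._x0p = sp.lambdify((ps,), x0.jacobian(ps) if ps else sp.zeros(len(xs), 0), modules=mods)

    # thin, shape-stable wrappers around the lambdified callables
    def f(self, t, x, p):
        return np.asarray(self._f(t, x, p), dtype=float).reshape(-1)

    def dfdx(self, t, x, p):
        return np.asarray(self._fx(t, x, p), dtype=float).reshape(self.spec.n_states, self.spec.n_states)

    def dfdp(self, t, x, p):
        return np.asarray(self._fp(t, x, p), dtype=float).reshape(self.spec.n_states, self.spec.n_parameters)

    def h(self, t, x, p):
        return np.asarray(self._h(t, x, p), dtype=float).reshape(-1)

    def dhdx(self, t, x, p):
        return np.asarray(self._hx(t, x, p), dtype=float).reshape(self.spec.n_observables, self.spec.n_states)

    def dhdp(self, t, x, p):
        return np.asarray(self._hp(t, x, p), dtype=float).reshape(self.spec.n_observables, self.spec.n_parameters)

    def x0(self, p):
        return np.asarray(self._x0(p), dtype=float).reshape(-1)

    def dx0dp(self, p):
        return np.asarray(self._x0p(p), dtype=float).reshape(self.spec.n_states, self.spec.n_parameters)

    def simulate(
        self,
        theta: Sequence[float],
        times: Sequence[float],
        with_sensitivities: bool = False,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ) -> SimulationResult:
        """Integrate the model at ``theta`` (estimation scale) over ``times``.

        Sensitivities, when requested, are propagated through the augmented
        ODE system and returned with respect to the estimation-scale
        parameters (chain rule ln(10)*theta_lin applied for log10 parameters).
        Integration failures are reported through ``success``, never raised,
        so multi-start optimization survives pathological parameter draws.
        """
        spec = self.spec
        times = np.asarray(times, dtype=float)
        nx, nth, ny = spec.n_states, spec.n_parameters, spec.n_observables
        if times.size == 0:
            return SimulationResult(
                times=times, states=np.zeros((nx, 0)), observables=np.zeros((ny, 0)),
                observable_sensitivities=np.zeros((ny, 0, nth)) if with_sensitivities else None,
                success=True,
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        p = spec.to_linear(np.asarray(theta, dtype=float))
        x_init = self.x0(p)

        def guard(z):
            if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > STATE_OVERFLOW:
                raise _SimulationDiverged("state diverged")

        if with_sensitivities:
            s_init = self.dx0dp(p).ravel()
            z0 = np.concatenate([x_init, s_init])

            def rhs(t, z):
                guard(z)
                x = z[:nx]
                s = z[nx:].reshape(nx, nth)
                fx = self.dfdx(t, x, p)
                return np.concatenate([self.f(t, x, p), (fx @ s + self.dfdp(t, x, p)).ravel()])
        else:
            z0 = x_init

            def rhs(t, z):
                guard(z)
                return self.f(t, z, p)

        t_end = float(times[-1])
        t_begin = min(spec.t0, float(times[0]))
        try:
            sol = solve_ivp(
                rhs, (t_begin, t_end), z0, t_eval=times, method=method,
                rtol=rtol, atol=atol,
            )
        except (_SimulationDiverged, ValueError, FloatingPointError, OverflowError) as err:
            return SimulationResult(times, np.zeros((nx, 0)), np.zeros((ny, 0)), None,
                                    success=False, message=str(err))
        if not sol.success or sol.y.shape[1] != times.size or not np.all(np.isfinite(sol.y)):
            return SimulationResult(times, np.zeros((nx, 0)), np.zeros((ny, 0)), None,
                                    success=False, message=sol.message)

        xs = sol.y[:nx]
        obs = np.empty((ny, times.size))
        for k, tk in enumerate(times):
            obs[:, k] = self.h(tk, xs[:, k], p)

        sens = None
        if with_sensitivities:
            # chain dy/dtheta = dh/dx S + dh/dtheta, then to the estimation scale
            scale = np.array([LN10 * p[j] if s == "log10" else 1.0
                              for j, s in enumerate(spec.scales)])
            sens = np.empty((ny, times.size, nth))
            for k, tk in enumerate(times):
                s = sol.y[nx:, k].reshape(nx, nth)
                sens[:, k, :] = (self.dhdx(tk, xs[:, k], p) @ s + self.dhdp(tk, xs[:, k], p)) * scale
            if not np.all(np.isfinite(sens)):
                return SimulationResult(times, xs, obs, None, success=False,
                                        message="non-finite sensitivities")
        return SimulationResult(times, xs, obs, sens, success=True)


_COMPILE_CACHE: dict[int, CompiledModel] = {}


def compile_model(spec: ODEModelSpec) -> CompiledModel:
    """Build (and memoize) the numerical evaluators for a model spec."""
    key = id(spec)
    model = _COMPILE_CACHE.get(key)
    if model is None or model.spec is not spec:
        model = CompiledModel(spec)
        _COMPILE_CACHE[key] = model
    return model


def simulate(
    spec: ODEModelSpec | CompiledModel,
    theta: Sequence[float],
    times: Sequence[float],
    with_sensitivities: bool = False,
    **kwargs,
) -> SimulationResult:
    """Simulate a model (compiling it on first use)."""
    model = spec if isinstance(spec, CompiledModel) else compile_model(spec)
    return model.simulate(theta, times, with_sensitivities=with_sensitivities, **kwargs)
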