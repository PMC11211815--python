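"""Multi-start estimation, confidence regions, MCMC and mapping diagnostics.

The global maximum-likelihood estimate is sought by repeated bounded local
optimization from Latin-hypercube start points; start quality is judged by the
likelihood-ratio statistic Lambda(theta) = 2 (J(theta) - J(theta*)), which is
asymptotically chi-square with df = n_theta degrees of freedom, giving the
confidence region {theta : Lambda(theta) <= Delta_alpha}.  Posterior
uncertainty of both parameters and the reconstructed measurement mappings is
quantified with an adaptive Metropolis sampler over theta alone: observable
parameters are profiled out by the hierarchical inner solvers at every step,
and pointwise credibility bands of the mapping are percentile envelopes of
the per-sample optimal splines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .inner import solve_inner_all
from .objective import HierarchicalObjective, JointObjective
from .spline import SplineMapping, eval_spline

__all__ = [
    "StartRecord",
    "FitResult",
    "SampleResult",
    "ConfidenceRegion",
    "multistart_fit",
    "likelihood_ratio_statistic",
    "lr_threshold",
    "classify_converged",
    "sample_posterior",
    "classify_mapping",
    "parameter_distance",
]


@dataclass
class StartRecord:
    theta0: np.ndarray
    theta: np.ndarray
    value: float
    grad_norm: float
    n_evaluations: int
    n_iterations: int
    success: bool
    message: str = ""


@dataclass
class FitResult:
    """Multi-start optimization outcome, starts sorted by final objective."""

    starts: list[StartRecord]
    theta_star: np.ndarray
    value_star: float
    seed: int
    mode: str                       # "gradient" or "gradient_free"
    converged: np.ndarray | None = None

    @property
    def n_starts(self) -> int:
        return len(self.starts)

    def sorted_values(self) -> np.ndarray:
        """Final objective values in increasing order (waterfall diagnostic)."""
        return np.array([s.value for s in self.starts])


@dataclass
class ConfidenceRegion:
    """Likelihood-ratio confidence region at significance alpha."""

    alpha: float
    df: int
    value_star: float

    @property
    def threshold(self) -> float:
        return lr_threshold(self.alpha, self.df)

    def contains(self, value_at_theta: float) -> bool:
        return likelihood_ratio_statistic(value_at_theta, self.value_star) <= self.threshold


def draw_starts(lower, upper, n_starts: int, seed: int) -> np.ndarray:
    """Latin-hypercube start points over the (scaled) parameter box."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    sampler = qmc.LatinHypercube(d=lower.size, seed=seed)
    return qmc.scale(sampler.random(n_starts), lower, upper)


def _minimize_gradient(obj: HierarchicalObjective, theta0, bounds, options,
                       max_restarts: int = 3):
    # longer line search tolerates the mild non-smoothness of adaptive re-gridding
    opts = {"maxiter": 500, "maxls": 50}
    opts.update(options or {})
    res = optimize.minimize(obj.value_and_grad, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    # a kink can fire the relative-reduction stop far from a stationary point;
    # fresh-memory restarts push through while they keep improving
    for _ in range(max_restarts):
        again = optimize.minimize(obj.value_and_grad, res.x, jac=True,
                                  method="L-BFGS-B", bounds=bounds, options=opts)
        if not np.isfinite(again.fun) or again.fun >= res.fun - 1e-10 * max(1.0, abs(res.fun)):
            if again.fun < res.fun:
                res = again
            break
        res = again
    return res


def _minimize_free(obj: HierarchicalObjective, theta0, bounds, options):
    opts = {"maxiter": 2000}
    opts.update(options or {})
    return optimize.minimize(obj, theta0, method="Powell", bounds=bounds, options=opts)


def multistart_fit(obj: HierarchicalObjective, n_starts: int, seed: int,
                   mode: str = "gradient", options: dict | None = None,
                   starts: np.ndarray | None = None) -> FitResult:
    """Run ``n_starts`` bounded local optimizations from Latin-hypercube draws.

    ``mode="gradient"`` uses a bounded quasi-Newton optimizer consuming the
    analytic hierarchical gradient; ``mode="gradient_free"`` uses the Powell
    direction-set method on the same objective (the efficiency baseline).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    if mode not in ("gradient", "gradient_free"):
        raise ValueError(f"unknown optimization mode {mode!r}")
    lower, upper = obj.spec.sample_bounds()
    if starts is None:
        starts = draw_starts(lower, upper, n_starts, seed)
    else:
        starts = np.atleast_2d(np.asarray(starts, float))
        if starts.shape != (n_starts, lower.size):
            raise ValueError("explicit starts must have shape (n_starts, n_parameters)")
    bounds = list(zip(lower, upper))
    run = _minimize_gradient if mode == "gradient" else _minimize_free

    records: list[StartRecord] = []
    for theta0 in starts:
        n0 = obj.n_evaluations
        try:
            res = run(obj, theta0, bounds, options)
            grad_norm = (float(np.linalg.norm(res.jac)) if getattr(res, "jac", None) is not None
                         else np.nan)
            records.append(StartRecord(
                theta0=theta0.copy(), theta=np.asarray(res.x, float),
                value=float(res.fun), grad_norm=grad_norm,
                n_evaluations=obj.n_evaluations - n0,
                n_iterations=int(getattr(res, "nit", 0)), success=bool(res.success),
                message=str(res.message)))
        except Exception as err:  # keep the multi-start alive on a bad draw
            records.append(StartRecord(theta0=theta0.copy(), theta=theta0.copy(),
                                       value=np.inf, grad_norm=np.nan,
                                       n_evaluations=obj.n_evaluations - n0,
                                       n_iterations=0, success=False, message=str(err)))
    records.sort(key=lambda r: r.value)
    if not np.isfinite(records[0].value):
        details = "; ".join(r.message for r in records[:3])
        raise RuntimeError(f"all {n_starts} starts failed ({details})")
    return FitResult(starts=records, theta_star=records[0].theta.copy(),
                     value_star=records[0].value, seed=seed, mode=mode)


def likelihood_ratio_statistic(value_at_theta: float, value_star: float,
                               tol: float = 1e-8) -> float:
    """Lambda = 2 (J(theta) - J(theta*)), clipped at zero."""
    if not (np.isfinite(value_at_theta) and np.isfinite(value_star)):
        raise ValueError("both objective values must be finite")
    if value_at_theta < value_star - tol:
        raise ValueError(
            f"J(theta)={value_at_theta} is below the reference optimum {value_star}; "
            "the reference is not the global minimum")
    return max(2.0 * (value_at_theta - value_star), 0.0)


def lr_threshold(alpha: float, df: int) -> float:
    """Delta_alpha: the alpha-quantile of chi-square with ``df`` degrees of freedom."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.chi2.ppf(alpha, df))


def classify_converged(fit: FitResult, alpha: float = 0.95,
                       df: int | None = None) -> np.ndarray:
    """Flag starts whose optimum lies in the alpha confidence region of theta*."""
    if not np.isfinite(fit.value_star):
        raise ValueError("fit has no finite optimum")
    if df is None:
        df = fit.theta_star.size
    delta = lr_threshold(alpha, df)
    flags = np.array([
        np.isfinite(s.value)
        and likelihood_ratio_statistic(max(s.value, fit.value_star), fit.value_star) <= delta
        for s in fit.starts
    ])
    fit.converged = flags
    return flags


def parameter_distance(theta_hat, theta_true) -> float:
    """L2 distance normalized by the parameter count, on the estimation scale."""
    a = np.asarray(theta_hat, float)
    b = np.asarray(theta_true, float)
    if a.shape != b.shape:
        raise ValueError("parameter vectors must have equal length")
    return float(np.linalg.norm(a - b) / a.size)


# ---------------------------------------------------------------------------
# adaptive Metropolis sampling with profiled mappings
# ---------------------------------------------------------------------------

@dataclass
class SampleResult:
    """MCMC output: chain, per-sample optimal mappings and credibility bands."""

    chain: np.ndarray                 # (n_retained, n_theta)
    log_posterior: np.ndarray         # (n_retained,)
    acceptance_rate: float
    thin: int
    seed: int
    mappings: dict[str, list[SplineMapping]] = field(default_factory=dict)
    bands: dict[str, dict] = field(default_factory=dict)
    parameter_names: tuple[str, ...] = ()


def sample_posterior(obj: HierarchicalObjective, theta_init, n_iter: int,
                     thin: int = 1, seed: int = 0, alpha: float = 0.95,
                     band_grid_size: int = 30, warmup_fraction: float = 0.2,
                     initial_step: float = 0.1) -> SampleResult:
    """Adaptive Metropolis over the mechanistic parameters.

    The posterior is the hierarchical likelihood under a uniform prior on the
    (log10) parameter box, so observable parameters are profiled out exactly
    at every step.  The proposal covariance is adapted from the chain history
    toward the standard 2.38^2/d scaling and frozen after the warm-up fraction
    to preserve asymptotic correctness.  For each retained sample the inner
    problems are re-solved to obtain that sample's optimal mapping; pointwise
    credibility bands are central percentile envelopes of the mapped values
    over a fixed per-observable evaluation grid.
    """
    rng = np.random.default_rng(seed)
    lower, upper = obj.spec.sample_bounds()
    theta = np.asarray(theta_init, float).copy()
    d = theta.size
    value = obj(theta)
    if not np.isfinite(value):
        raise ValueError("theta_init has non-finite objective")

    cov_scale = 2.38**2 / d
    eps = 1e-8 * np.eye(d)
    prop_cov = np.diag((initial_step * (upper - lower)) ** 2)
    chol = np.linalg.cholesky(prop_cov)
    warmup = int(warmup_fraction * n_iter)
    history = np.empty((n_iter, d))
    accepted = 0
    retained_theta, retained_logpost = [], []

    mean = theta.copy()
    m2 = np.zeros((d, d))     # running covariance accumulator

    for it in range(n_iter):
        prop = theta + chol @ rng.standard_normal(d)
        if np.all(prop >= lower) & np.all(prop <= upper):
            v_prop = obj(prop)
            if np.isfinite(v_prop) and np.log(rng.random()) < value - v_prop:
                theta, value = prop, v_prop
                accepted += 1
        history[it] = theta
        # running mean/covariance update, used for adaptation during warm-up
        delta = theta - mean
        mean += delta / (it + 1)
        m2 += np.outer(delta, theta - mean)
        if 50 <= it < warmup and (it + 1) % 25 == 0:
            emp_cov = m2 / it
            chol = np.linalg.cholesky(cov_scale * emp_cov + eps)
        if (it + 1) % thin == 0:
            retained_theta.append(theta.copy())
            retained_logpost.append(-value)

    if accepted == 0:
        raise RuntimeError("no accepted moves; check theta_init and proposal scale")

    chain = np.asarray(retained_theta)
    result = SampleResult(
        chain=chain, log_posterior=np.asarray(retained_logpost),
        acceptance_rate=accepted / n_iter, thin=thin, seed=seed,
        parameter_names=obj.spec.parameter_names,
    )

    # per-sample optimal mappings and percentile bands
    spline_ids = [c.observable_id for c in obj.configs
                  if c.mapping_class == "nonlinear_monotone"]
    if spline_ids:
        name_index = {n: i for i, n in enumerate(obj.spec.observable_names)}
        per_sample_maps: dict[str, list[SplineMapping]] = {oid: [] for oid in spline_ids}
        y_max = {oid: [] for oid in spline_ids}
        for th in chain:
            ev = obj.evaluate(th)
            if ev.inner is None:
                continue
            for oid in spline_ids:
                sol = ev.inner.get(oid)
                if sol is not None and sol.mapping is not None:
                    per_sample_maps[oid].append(sol.mapping)
                    t_idx = np.searchsorted(obj.times, obj.data.times(oid))
                    y_max[oid].append(
                        float(np.max(ev.simulation.observables[name_index[oid], t_idx])))
        lo_q, hi_q = 100 * (1 - alpha) / 2, 100 * (1 + alpha) / 2
        for oid in spline_ids:
            maps = per_sample_maps[oid]
            if not maps:
                continue
            # grid over the data-informed input range: up to the typical
            # (median across samples) largest simulated value at a data time
            grid = np.linspace(0.0, float(np.median(y_max[oid])), band_grid_size)
            values = np.array([eval_spline(m, grid) for m in maps])
            result.mappings[oid] = maps
            result.bands[oid] = {
                "grid": grid,
                "lower": np.percentile(values, lo_q, axis=0),
                "upper": np.percentile(values, hi_q, axis=0),
                "level": alpha,
            }
    return result


# ---------------------------------------------------------------------------
# mapping-shape classification
# ---------------------------------------------------------------------------

def classify_mapping(mapping: SplineMapping, data_range: tuple[float, float] | None = None,
                     tol_abs: float = 0.05, tol_affine: float = 0.05,
                     tol_zero: float | None = None) -> str:
    """Label a fitted mapping as quantitative, relative, censored-like or nonlinear.

    * ``quantitative``: the mapping is the identity within ``tol_abs`` over the
      data-covered input range;
    * ``relative``: the knot heights are affine in the knot bases within
      ``tol_affine`` (RMS residual of a line fit);
    * ``censored-like``: a run of >= 2 consecutive (near-)zero increments abuts
      either end of the grid (lower limit of detection or saturation);
    * ``nonlinear`` otherwise.

    ``tol_zero`` defaults to 1% of the largest increment, so "zero slope" is
    judged relative to the mapping's own scale (noisy fits rarely produce
    exact zeros).
    """
    c = mapping.knots
    heights = mapping.knot_heights
    if data_range is None:
        data_range = (0.0, float(c[-1]))
    # only intervals whose left edge lies below the largest data-covered input
    # are informed by data; increments beyond are extrapolation artifacts
    covered = np.concatenate([[0.0], c])[:-1] < data_range[1]
    c = c[covered]
    heights = heights[covered]
    increments = mapping.increments[covered]
    grid = np.linspace(max(0.0, data_range[0]), min(float(c[-1]), data_range[1]), 201)
    if np.max(np.abs(eval_spline(mapping, grid) - grid)) <= tol_abs:
        return "quantitative"
    design = np.column_stack([c, np.ones_like(c)])
    coef, *_ = np.linalg.lstsq(design, heights, rcond=None)
    if np.sqrt(np.mean((design @ coef - heights) ** 2)) <= tol_affine:
        return "relative"
    if tol_zero is None:
        tol_zero = 0.01 * float(np.max(increments, initial=0.0))
    zero = increments <= tol_zero
    leading = 0
    while leading < zero.size and zero[leading]:
        leading += 1
    trailing = 0
    while trailing < zero.size and zero[-1 - trailing]:
        trailing += 1
    if max(leading, trailing) >= 2:
        return "censored-like"
    return "nonlinear"
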