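"""Inner problems: affine closed forms, convex spline NNLS, noise estimation."""

import numpy as np
import pytest
from scipy.optimize import minimize

import semiquant as sq
from semiquant.inner import (
    SIGMA_FLOOR,
    MeasurementSet,
    ObservableConfig,
    gaussian_nll,
    solve_inner_all,
    solve_quantitative,
    solve_relative,
    solve_spline_inner,
)
from semiquant.spline import RegularizationConfig, SplineMapping, make_knot_grid, \
    regularization_penalty, spline_basis_matrix


def cfg_rel(**kw):
    return ObservableConfig("obs", mapping_class="relative", **kw)


def cfg_spline(n_knots=3, lam=0.0, **kw):
    return ObservableConfig("obs", mapping_class="nonlinear_monotone", n_knots=n_knots,
                            regularization=RegularizationConfig(lam), **kw)


class TestRelative:
    def test_exact_affine_data(self):
        y = np.linspace(0.2, 3.0, 8)
        sol = solve_relative(y, 2 * y + 1, cfg_rel())
        assert sol.parameters["scale"] == pytest.approx(2.0)
        assert sol.parameters["offset"] == pytest.approx(1.0)
        assert sol.sigma[0] == pytest.approx(SIGMA_FLOOR)

    def test_constant_measurements(self):
        y = np.linspace(0.2, 3.0, 6)
        sol = solve_relative(y, np.full(6, 4.2), cfg_rel())
        assert sol.parameters["scale"] == pytest.approx(0.0)
        assert sol.parameters["offset"] == pytest.approx(4.2)

    def test_degenerate_simulation_flagged(self):
        sol = solve_relative(np.full(5, 1.3), np.arange(5.0), cfg_rel())
        assert not sol.identifiable
        assert sol.parameters["scale"] == 0.0
        assert sol.parameters["offset"] == pytest.approx(2.0)

    def test_closed_form_matches_numerical_minimizer(self):
        # oracle: numerically minimize the Gaussian NLL over (a, b, log sigma)
        rng = np.random.default_rng(8)
        y = rng.uniform(0, 5, 12)
        z = 1.7 * y - 0.4 + rng.normal(0, 0.3, 12)
        sol = solve_relative(y, z, cfg_rel())

        def nll(v):
            a, b, logs = v
            return gaussian_nll(a * y + b - z, np.full_like(z, np.exp(logs)))

        res = minimize(nll, [1.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
        assert sol.parameters["scale"] == pytest.approx(res.x[0], abs=1e-6)
        assert sol.parameters["offset"] == pytest.approx(res.x[1], abs=1e-6)
        assert sol.sigma[0] == pytest.approx(np.exp(res.x[2]), abs=1e-6)
        assert sol.objective == pytest.approx(res.fun, abs=1e-6)

    def test_weighted_closed_form_with_known_sigmas(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 5, 10)
        z = 0.8 * y + 2.0 + rng.normal(0, 0.1, 10)
        sig = rng.uniform(0.05, 0.5, 10)
        sol = solve_relative(y, z, cfg_rel(), known_sigmas=sig)

        def nll(v):
            return gaussian_nll(v[0] * y + v[1] - z, sig)

        res = minimize(nll, [1.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-13})
        assert sol.parameters["scale"] == pytest.approx(res.x[0], abs=1e-6)
        assert sol.parameters["offset"] == pytest.approx(res.x[1], abs=1e-6)


class TestSplineInner:
    def test_identity_mapping_recovered_exactly(self):
        # noiseless data through the identity, lam=0, grid over the exact range
        y = np.linspace(0.4, 10.0, 25)
        cfg = cfg_spline(n_knots=5, lam=0.0, margin=0.0)
        sol = solve_spline_inner(y, y.copy(), cfg)
        dc = 10.0 / 5
        np.testing.assert_allclose(sol.parameters["increments"], dc, atol=1e-8)
        nt = y.size
        assert sol.objective == pytest.approx(
            nt * np.log(np.sqrt(2 * np.pi) * SIGMA_FLOOR), rel=1e-9)

    def test_all_zero_measurements(self):
        y = np.linspace(0.5, 4, 8)
        sol = solve_spline_inner(y, np.zeros(8), cfg_spline(n_knots=3, lam=0.0))
        np.testing.assert_allclose(sol.parameters["increments"], 0.0, atol=1e-12)
        assert sol.sigma[0] == SIGMA_FLOOR

    def test_matches_brute_force_grid_search(self):
        # tiny instance: exhaustive search over [0,2]^3 refined by a local polish
        rng = np.random.default_rng(11)
        y = np.array([0.5, 1.1, 1.9, 2.6, 3.0])
        z = np.array([0.3, 0.8, 1.1, 1.3, 1.6])
        cfg = cfg_spline(n_knots=3, lam=0.2, noise_mode="known", known_sigma=0.4)
        sol = solve_spline_inner(y, z, cfg)
        knots = make_knot_grid(y, 3, cfg.margin)
        template = SplineMapping(knots, np.zeros(3))
        b = spline_basis_matrix(template, y)

        def objective(xi):
            pen, _ = regularization_penalty(xi, cfg.regularization)
            return gaussian_nll(b @ xi - z, np.full_like(z, 0.4)) + pen

        grid = np.arange(0.0, 2.0, 0.05)
        best, best_val = None, np.inf
        for a in grid:
            for bb in grid:
                for c in grid:
                    v = objective(np.array([a, bb, c]))
                    if v < best_val:
                        best, best_val = np.array([a, bb, c]), v
        res = minimize(objective, best, method="L-BFGS-B",
                       bounds=[(0, None)] * 3, options={"ftol": 1e-15, "gtol": 1e-12})
        np.testing.assert_allclose(sol.parameters["increments"], res.x, atol=1e-3)
        assert sol.objective == pytest.approx(res.fun, abs=1e-6)

    def test_kkt_conditions_at_optimum(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = np.sort(rng.uniform(0.1, 5, 14))
            z = np.sqrt(y) + rng.normal(0, 0.1, 14)
            cfg = cfg_spline(n_knots=6, lam=0.3, noise_mode="known", known_sigma=0.1)
            sol = solve_spline_inner(y, z, cfg)
            xi = sol.parameters["increments"]
            knots = sol.mapping.knots
            b = spline_basis_matrix(SplineMapping(knots, np.zeros_like(xi)), y)
            pen_grad = regularization_penalty(xi, cfg.regularization)[1]
            grad = b.T @ (b @ xi - z) / 0.1**2 + pen_grad
            at_bound = xi <= 1e-12
            assert np.all(grad[at_bound] >= -1e-6)
            assert np.all(np.abs(grad[~at_bound]) <= 1e-6)

    def test_convexity_probe(self):
        rng = np.random.default_rng(17)
        y = np.sort(rng.uniform(0.1, 4, 12))
        z = 1.3 * y + rng.normal(0, 0.2, 12)
        cfg = cfg_spline(n_knots=4, lam=0.5, noise_mode="known", known_sigma=0.2)
        sol = solve_spline_inner(y, z, cfg)
        knots = sol.mapping.knots
        b = spline_basis_matrix(SplineMapping(knots, np.zeros(4)), y)

        def objective(xi):
            return gaussian_nll(b @ xi - z, np.full_like(z, 0.2)) \
                + regularization_penalty(xi, cfg.regularization)[0]

        opt = objective(sol.parameters["increments"])
        for _ in range(100):
            p1, p2 = rng.uniform(0, 3, 4), rng.uniform(0, 3, 4)
            w = rng.random()
            mix = objective(w * p1 + (1 - w) * p2)
            assert mix <= max(objective(p1), objective(p2)) + 1e-9
        assert all(opt <= objective(rng.uniform(0, 3, 4)) + 1e-9 for _ in range(1000))

    def test_spline_nests_origin_affine(self):
        # at lam=0 the spline fit is at least as good as the best line through 0
        rng = np.random.default_rng(23)
        y = np.sort(rng.uniform(0.2, 4, 15))
        z = 2.0 * y / (0.5 + y) + rng.normal(0, 0.05, 15)
        cfg = cfg_spline(n_knots=5, lam=0.0, noise_mode="known", known_sigma=0.05)
        sol = solve_spline_inner(y, z, cfg)
        a = float(y @ z / (y @ y))
        assert sol.objective <= gaussian_nll(a * y - z, np.full_like(z, 0.05)) + 1e-9

    def test_estimated_sigma_is_rms_residual(self):
        rng = np.random.default_rng(29)
        y = np.sort(rng.uniform(0.2, 4, 20))
        z = y**2 + rng.normal(0, 0.3, 20)
        sol = solve_spline_inner(y, z, cfg_spline(n_knots=5, lam=0.7))
        assert sol.sigma[0] == pytest.approx(np.sqrt(np.mean(sol.residuals**2)), rel=1e-9)


class TestSolveAll:
    def make_problem(self):
        spec = sq.ODEModelSpec(
            name="three_obs", state_names=("A",), parameter_names=("k",),
            rhs_exprs=("-k*A",), init_exprs=("2",),
            observable_names=("q", "r", "s"), observable_exprs=("A", "A", "A"),
            lower_bounds=(-2.0,), upper_bounds=(1.0,), scales=("log10",))
        times = np.linspace(0.2, 5, 12)
        sim = sq.simulate(spec, [-0.3], times)
        rng = np.random.default_rng(2)
        data = MeasurementSet()
        for k, t in enumerate(times):
            a = sim.observables[0, k]
            data.add("q", t, a + rng.normal(0, 0.05))
            data.add("r", t, 2 * a + 1 + rng.normal(0, 0.05))
            data.add("s", t, np.sqrt(a) + rng.normal(0, 0.05))
        configs = [
            ObservableConfig("q", mapping_class="quantitative"),
            ObservableConfig("r", mapping_class="relative"),
            ObservableConfig("s", mapping_class="nonlinear_monotone", n_knots=4),
        ]
        return spec, sim, data, configs

    def test_additive_and_order_invariant(self):
        spec, sim, data, configs = self.make_problem()
        sols = solve_inner_all(sim, data, configs, spec.observable_names)
        assert set(sols) == {"q", "r", "s"}
        total = sum(s.objective for s in sols.values())
        sols_perm = solve_inner_all(sim, data, list(reversed(configs)),
                                    spec.observable_names)
        total_perm = sum(s.objective for s in sols_perm.values())
        assert total == pytest.approx(total_perm, abs=1e-12)
        for oid in sols:
            np.testing.assert_array_equal(
                sols[oid].mapped, sols_perm[oid].mapped)

    def test_joint_minimization_agrees_with_per_observable(self):
        # oracle: minimize (a, b) for the relative observable numerically while
        # the others are solved in closed form; total J must match
        spec, sim, data, configs = self.make_problem()
        sols = solve_inner_all(sim, data, configs, spec.observable_names)
        y = sim.observables[1, np.searchsorted(sim.times, data.times("r"))]
        z = data.values("r")

        def nll(v):
            res = v[0] * y + v[1] - z
            s = max(np.sqrt(np.mean(res**2)), SIGMA_FLOOR)
            return gaussian_nll(res, np.full_like(z, s))

        res = minimize(nll, [1.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert sols["r"].objective == pytest.approx(res.fun, abs=1e-6)

    def test_missing_config_raises(self):
        spec, sim, data, configs = self.make_problem()
        with pytest.raises(KeyError, match="q"):
            solve_inner_all(sim, data, configs[1:], spec.observable_names)

    def test_quantitative_identity(self):
        y = np.linspace(1, 3, 6)
        sol = solve_quantitative(y, y + 0.1, ObservableConfig("obs"))
        np.testing.assert_allclose(sol.slopes, 1.0)
        np.testing.assert_allclose(sol.residuals, -0.1)


def test_measurement_set_round_trip_via_dataframe():
    rng = np.random.default_rng(0)
    data = MeasurementSet()
    for t, v in zip(np.arange(5.0), rng.normal(size=5)):
        data.add("a", t, v, 0.1)
        data.add("b", t, 2 * v)
    df = data.to_dataframe()
    assert list(df.columns) == ["observableId", "time", "measurement", "noiseValue"]
    assert len(df) == 10
    np.testing.assert_array_equal(data.sigmas("a"), 0.1)
    assert data.sigmas("b") is None
    np.testing.assert_array_equal(data.all_times(), np.arange(5.0))
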