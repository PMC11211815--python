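"""Hierarchical objective: value assembly, analytic gradient, joint baseline."""

import numpy as np
import pytest

import semiquant as sq
from semiquant.benchmarks import FRET_TRUE, make_t1_problem, t1_true_mapping
from semiquant.inner import MeasurementSet, ObservableConfig, gaussian_nll
from semiquant.objective import HierarchicalObjective, JointObjective


@pytest.fixture(scope="module")
def t1_known_noise():
    spec, dataset, configs = make_t1_problem(seed=2)
    return spec, dataset, configs


class TestEvaluate:
    def test_noiseless_known_sigma_gives_normalization_constant(self):
        spec, dataset, _ = make_t1_problem(seed=0)
        sigma = 0.07
        sim = sq.simulate(spec, dataset.theta_true, dataset.times)
        g = t1_true_mapping()
        data = MeasurementSet()
        for t, y in zip(dataset.times, sim.observables[0]):
            data.add("frac_active", t, float(g(y)))
        cfgs = [ObservableConfig("frac_active", mapping_class="quantitative",
                                 noise_mode="known", known_sigma=sigma)]
        # identity comparison needs the mapped data as the observable itself:
        # use a quantitative config on mapped values by mapping the observable
        data_q = MeasurementSet()
        for t, y in zip(dataset.times, sim.observables[0]):
            data_q.add("frac_active", t, float(y))
        obj = HierarchicalObjective(spec, data_q, cfgs)
        ev = obj.evaluate(dataset.theta_true)
        nt = dataset.times.size
        expected = nt * np.log(np.sqrt(2 * np.pi) * sigma)
        assert ev.value == pytest.approx(expected, abs=1e-6)

    def test_duplicated_measurements_double_data_terms(self):
        # with the penalty disabled, the inner optimum is invariant under
        # duplication and the data-dependent part of J doubles exactly
        from semiquant.spline import RegularizationConfig
        spec, dataset, _ = make_t1_problem(seed=2, regularization=0.0)
        configs = [ObservableConfig("frac_active", mapping_class="nonlinear_monotone",
                                    n_knots=10,
                                    regularization=RegularizationConfig(0.0))]
        obj = HierarchicalObjective(spec, dataset.data, configs)
        doubled = MeasurementSet()
        for t, z, s in zip(dataset.data.times("frac_active"),
                           dataset.data.values("frac_active"),
                           dataset.data.sigmas("frac_active")):
            doubled.add("frac_active", t, z, s)
            doubled.add("frac_active", t + 1e-9, z, s)
        obj2 = HierarchicalObjective(spec, doubled, configs)
        th = dataset.theta_true
        ev1, ev2 = obj.evaluate(th), obj2.evaluate(th)
        assert ev2.value == pytest.approx(2 * ev1.value, rel=1e-6)

    def test_additivity_of_inner_objectives(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        obj = HierarchicalObjective(spec, dataset.data, configs)
        ev = obj.evaluate(dataset.theta_true)
        assert ev.value == pytest.approx(
            sum(s.objective for s in ev.inner.values()), abs=1e-12)

    def test_flat_nll_oracle(self, t1_known_noise):
        # independent flat (non-hierarchical) NLL evaluated at (theta, psi*)
        spec, dataset, configs = t1_known_noise
        obj = HierarchicalObjective(spec, dataset.data, configs)
        th = dataset.theta_true
        ev = obj.evaluate(th)
        sol = ev.inner["frac_active"]
        y = ev.simulation.observables[0]
        xi = sol.parameters["increments"]
        mapping = sol.mapping
        mapped = mapping(y)
        lam = configs[0].regularization.effective_strength
        flat = gaussian_nll(mapped - dataset.data.values("frac_active"), sol.sigma) \
            + 0.5 * lam * np.sum((xi - xi.mean())**2)
        assert ev.value == pytest.approx(flat, abs=1e-10)

    def test_failed_simulation_maps_to_infinity(self):
        spec = sq.ODEModelSpec(
            name="blowup", state_names=("A",), parameter_names=("k",),
            rhs_exprs=("k*A*A",), init_exprs=("1",), observable_names=("o",),
            observable_exprs=("A",), lower_bounds=(-1.0,), upper_bounds=(6.0,),
            scales=("lin",))
        data = MeasurementSet([("o", 1.0, 1.0), ("o", 2.0, 2.0), ("o", 3.0, 2.5)])
        obj = HierarchicalObjective(spec, data, [ObservableConfig("o")])
        ev = obj.evaluate(np.array([1e5]))
        assert ev.value == np.inf and ev.gradient is None


class TestGradient:
    def test_zero_at_perfect_fit(self):
        spec, dataset, _ = make_t1_problem(seed=0)
        sim = sq.simulate(spec, dataset.theta_true, dataset.times)
        data = MeasurementSet()
        for t, y in zip(dataset.times, sim.observables[0]):
            data.add("frac_active", t, float(y), 0.02)
        cfgs = [ObservableConfig("frac_active", mapping_class="quantitative",
                                 noise_mode="known", known_sigma=0.02)]
        obj = HierarchicalObjective(spec, data, cfgs)
        _, grad = obj.value_and_grad(dataset.theta_true)
        assert np.linalg.norm(grad) < 1e-4

    def test_unused_parameter_has_zero_gradient(self, t1_known_noise):
        # alpha and beta never enter the spline-observable likelihood
        spec, dataset, configs = t1_known_noise
        obj = HierarchicalObjective(spec, dataset.data, configs)
        _, grad = obj.value_and_grad(dataset.theta_true)
        assert grad[2] == 0.0 and grad[3] == 0.0

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_finite_differences_of_full_hierarchical_map(self, trial,
                                                                 t1_known_noise):
        # operational envelope-theorem check: inner problems re-solved at every
        # perturbed theta, knot grid frozen during differencing
        spec, dataset, configs = t1_known_noise
        rng = np.random.default_rng(100 + trial)
        lo, up = spec.sample_bounds()
        # tight integrator tolerances keep solver noise below the FD step
        base = HierarchicalObjective(spec, dataset.data, configs,
                                     rtol=1e-11, atol=1e-13)
        theta = lo + rng.random(4) * (up - lo)
        obj = base.with_grids(base.freeze_grids(theta))
        v, g = obj.value_and_grad(theta)
        h = 1e-5
        fd = np.zeros(4)
        for j in range(4):
            e = np.zeros(4); e[j] = h
            fd[j] = (obj(theta + e) - obj(theta - e)) / (2 * h)
        assert np.linalg.norm(g - fd) <= 1e-4 * max(np.linalg.norm(fd), 1e-8)

    def test_directional_derivatives_along_random_directions(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs,
                                     rtol=1e-11, atol=1e-13)
        theta = dataset.theta_true + 0.1
        obj = base.with_grids(base.freeze_grids(theta))
        _, g = obj.value_and_grad(theta)
        rng = np.random.default_rng(0)
        h = 1e-5
        for _ in range(10):
            d = rng.standard_normal(4)
            d /= np.linalg.norm(d)
            fd = (obj(theta + h * d) - obj(theta - h * d)) / (2 * h)
            assert fd == pytest.approx(float(g @ d), rel=1e-4, abs=1e-7)

    def test_envelope_property_second_order(self, t1_known_noise):
        # perturbing the inner optimum changes J only at second order
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs)
        theta = dataset.theta_true
        grids = base.freeze_grids(theta)
        obj = base.with_grids(grids)
        joint = JointObjective(spec, dataset.data, configs, knot_grids=grids)
        ev = obj.evaluate(theta)
        xi = ev.inner["frac_active"].parameters["increments"]
        rng = np.random.default_rng(1)
        d = rng.random(xi.size) + 0.1        # feasible direction (xi > 0 stays)
        deltas = np.array([1e-3, 3e-3, 1e-2, 3e-2])
        diffs = []
        for dl in deltas:
            v = joint.pack(theta, {"frac_active": xi + dl * d})
            diffs.append(joint(v) - ev.value)
        diffs = np.array(diffs)
        assert np.all(diffs > 0)
        slope = np.polyfit(np.log(deltas), np.log(diffs), 1)[0]
        assert slope >= 1.9


class TestJoint:
    def test_value_agrees_at_inner_optimum(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs)
        theta = dataset.theta_true
        grids = base.freeze_grids(theta)
        obj = base.with_grids(grids)
        joint = JointObjective(spec, dataset.data, configs, knot_grids=grids)
        ev = obj.evaluate(theta)
        v = joint.pack(theta, {"frac_active": ev.inner["frac_active"].parameters["increments"]})
        assert joint(v) == pytest.approx(ev.value, abs=1e-6)

    def test_joint_gradient_near_zero_on_inactive_psi_at_optimum(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs,
                                     rtol=1e-11, atol=1e-13)
        theta = dataset.theta_true
        grids = base.freeze_grids(theta)
        joint = JointObjective(spec, dataset.data, configs, knot_grids=grids,
                               rtol=1e-11, atol=1e-13)
        ev = base.with_grids(grids).evaluate(theta)
        xi = ev.inner["frac_active"].parameters["increments"]
        v = joint.pack(theta, {"frac_active": xi})
        _, grad = joint.value_and_grad(v)
        psi_grad = grad[4:]
        inactive = xi > 1e-10
        assert np.all(np.abs(psi_grad[inactive]) < 1e-4)
        assert np.all(psi_grad[~inactive] > -1e-4)

    def test_joint_gradient_matches_finite_differences(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs)
        grids = base.freeze_grids(dataset.theta_true)
        joint = JointObjective(spec, dataset.data, configs, knot_grids=grids)
        rng = np.random.default_rng(6)
        v = joint.pack(dataset.theta_true + 0.05,
                       {"frac_active": rng.uniform(0.05, 0.3, 10)})
        val, g = joint.value_and_grad(v)
        h = 1e-6
        for j in range(v.size):
            e = np.zeros(v.size); e[j] = h
            fd = (joint(v + e) - joint(v - e)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=2e-4, abs=1e-6)

    def test_hierarchical_below_joint_everywhere(self, t1_known_noise):
        spec, dataset, configs = t1_known_noise
        base = HierarchicalObjective(spec, dataset.data, configs)
        grids = base.freeze_grids(dataset.theta_true)
        obj = base.with_grids(grids)
        joint = JointObjective(spec, dataset.data, configs, knot_grids=grids)
        rng = np.random.default_rng(7)
        lo, up = spec.sample_bounds()
        for _ in range(10):
            th = lo + rng.random(4) * (up - lo)
            xi = rng.uniform(0, 0.6, 10)
            assert obj(th) <= joint(joint.pack(th, {"frac_active": xi})) + 1e-7


def test_evaluation_counter_and_trace(t1_known_noise):
    spec, dataset, configs = t1_known_noise
    obj = HierarchicalObjective(spec, dataset.data, configs)
    obj.reset_counters()
    obj(dataset.theta_true)
    obj.value_and_grad(dataset.theta_true)
    assert obj.n_evaluations == 2
    assert len(obj.trace) == 2 and obj.trace[0][1] == pytest.approx(obj.trace[1][1], abs=1e-6)
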