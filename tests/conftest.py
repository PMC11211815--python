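import numpy as np
import pytest

import semiquant as sq
from semiquant.benchmarks import make_t1_problem


@pytest.fixture(scope="session")
def t1_problem():
    """Default T1 problem: model spec, seeded dataset, spline observable config."""
    return make_t1_problem(seed=1)


@pytest.fixture(scope="session")
def t1_objective(t1_problem):
    spec, dataset, configs = t1_problem
    return sq.HierarchicalObjective(spec, dataset.data, configs)


@pytest.fixture(scope="session")
def t1_fit(t1_objective):
    """A modest multi-start fit on the default T1 problem, shared across tests."""
    return sq.multistart_fit(t1_objective, n_starts=12, seed=11)


@pytest.fixture(scope="session")
def t1_fit50(t1_objective):
    """The 50-start reference fit used for recovery and coverage checks."""
    return sq.multistart_fit(t1_objective, n_starts=50, seed=7)


@pytest.fixture(scope="session")
def decay_model():
    """One-state exponential decay with closed-form solution y = exp(-k t)."""
    return sq.ODEModelSpec(
        name="decay",
        state_names=("A",),
        parameter_names=("k",),
        rhs_exprs=("-k*A",),
        init_exprs=("1",),
        observable_names=("obs_a",),
        observable_exprs=("A",),
        lower_bounds=(-3.0,),
        upper_bounds=(2.0,),
        scales=("log10",),
    )
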