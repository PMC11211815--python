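"""Bundled synthetic benchmark problems and data generation.

Two fully synthetic exemplars ship with the package so every experiment runs
without downloads:

* **T1**, a FRET probe-activation model: inactive probes P are activated by a
  forward enzyme and deactivated by a reverse enzyme (both folded into lumped
  first-order rates), and the fraction of active probes is read out through
  ratiometric imaging, whose calibration g(P*) = alpha * P*/(PTOT - P*) + beta
  is strongly nonlinear near saturation.
* a three-observable **cascade** of first-order conversions, each observable
  read through a different monotone nonlinear mapping — the multi-observable
  analog used for credibility-band experiments.

Datasets are produced by simulating at the true parameters, pushing each
observable through its (true) monotone mapping, and adding i.i.d. Gaussian
noise on the measurement scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .inner import MeasurementSet, ObservableConfig
from .models import ODEModelSpec, simulate
from .spline import RegularizationConfig

__all__ = [
    "FretTruth",
    "FRET_TRUE",
    "build_fret_model",
    "fret_mapping",
    "t1_true_mapping",
    "t1_times",
    "MappingLibraryEntry",
    "mapping_library",
    "build_cascade_model",
    "CASCADE_TRUE",
    "cascade_true_mappings",
    "cascade_times",
    "SyntheticDataset",
    "generate_dataset",
    "make_t1_problem",
    "make_cascade_problem",
]


# ---------------------------------------------------------------------------
# T1: FRET probe activation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretTruth:
    """Data-generating configuration of the T1 exemplar."""

    ptot: float = 10.0           # total probe concentration (conc. units)
    k_act: float = 0.3           # lumped activation rate kf*Ef(0) (1/min)
    k_deact: float = 0.08        # lumped deactivation rate kr*Er (1/min)
    alpha: float = 1.0           # ratiometric gain (dimensionless)
    beta: float = 0.0            # ratiometric baseline (0: background-corrected ratios)
    sigma: float = 0.02          # measurement noise SD on the mapped scale
    stimulus_decay: float = 0.25  # known decay rate of the forward-enzyme pulse (1/min)

    def theta_scaled(self, spec: "ODEModelSpec") -> np.ndarray:
        return spec.to_scaled(np.array([self.k_act, self.k_deact, self.alpha, self.beta]))


FRET_TRUE = FretTruth()


def build_fret_model(ptot: float = FRET_TRUE.ptot,
                     stimulus_decay: float = FRET_TRUE.stimulus_decay) -> ODEModelSpec:
    """Two-state FRET probe-activation model with four estimable parameters.

    States P (inactive) and Pstar (active) interconvert; the sum
    P + Pstar = PTOT is conserved and the model observable is the active
    fraction Pstar/PTOT.  The forward enzyme is a transient stimulus: its
    activity decays as exp(-stimulus_decay * t) with a known (experimentally
    characterized) decay rate, so the active fraction is a pulse — it rises
    while the stimulus lasts and relaxes back afterwards.  The pulse shape is
    what makes the measurement mapping recoverable: a strictly monotone
    trajectory could be reproduced under any rate pair by bending the monotone
    mapping, whereas equal activities at different times must map to equal
    measurements.  With ``stimulus_decay=0`` the model reduces to the
    constant-enzyme two-state system with closed-form solution
    y(t) = k_act/(k_act+k_deact) * (1 - exp(-(k_act+k_deact) t)).

    The calibration parameters alpha and beta of the parametric ratiometric
    mapping are carried as estimable parameters (they parameterize the
    measurement, not the dynamics, and enter only through the data-generating
    mapping or a parametric-mapping observable variant).
    """
    drive = "k_act*exp(-S_DECAY*t)" if stimulus_decay != 0 else "k_act"
    return ODEModelSpec(
        name="t1_fret",
        state_names=("P", "Pstar"),
        parameter_names=("k_act", "k_deact", "alpha", "beta"),
        rhs_exprs=(f"-{drive}*P + k_deact*Pstar", f"{drive}*P - k_deact*Pstar"),
        init_exprs=("PTOT", "0"),
        observable_names=("frac_active",),
        observable_exprs=("Pstar/PTOT",),
        lower_bounds=(-2.0, -2.0, -2.0, -1.0),
        upper_bounds=(1.0, 1.0, 2.0, 3.0),
        scales=("log10", "log10", "log10", "lin"),
        constants=(("PTOT", float(ptot)), ("S_DECAY", float(stimulus_decay))),
    )


def fret_mapping(p_star, ptot: float, alpha: float, beta: float):
    """Ratiometric-imaging calibration g(P*) = alpha * P*/(PTOT - P*) + beta.

    Strictly increasing on [0, PTOT) with a pole at P* = PTOT; equals beta at
    P* = 0.
    """
    p = np.asarray(p_star, dtype=float)
    if np.any(p < 0) or np.any(p >= ptot):
        raise ValueError("active probe concentration must satisfy 0 <= P* < PTOT")
    out = alpha * p / (ptot - p) + beta
    return float(out) if np.ndim(p_star) == 0 else out


def t1_true_mapping(truth: FretTruth = FRET_TRUE) -> Callable[[np.ndarray], np.ndarray]:
    """The T1 generating mapping on the observable scale (active fraction y)."""

    def g(y):
        return fret_mapping(np.asarray(y, float) * truth.ptot, truth.ptot,
                            truth.alpha, truth.beta)

    return g


def t1_times(n_times: int = 12) -> np.ndarray:
    """Log-spaced sampling grid covering the activation pulse (minutes)."""
    return np.geomspace(0.5, 40.0, n_times)


# ---------------------------------------------------------------------------
# monotone mapping library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappingLibraryEntry:
    name: str
    func: Callable[[np.ndarray], np.ndarray]
    params: dict
    input_range: tuple[float, float]

    def check_monotone(self, n_grid: int = 1000, tol: float = 0.0) -> bool:
        x = np.linspace(*self.input_range, n_grid)
        return bool(np.all(np.diff(self.func(x)) >= -tol))


def mapping_library() -> list[MappingLibraryEntry]:
    """Monotone synthetic measurement mappings used for data generation."""
    return [
        MappingLibraryEntry("identity", lambda x: np.asarray(x, float), {}, (0.0, 10.0)),
        MappingLibraryEntry("affine", lambda x: 2.0 * np.asarray(x, float) + 0.5,
                            {"scale": 2.0, "offset": 0.5}, (0.0, 10.0)),
        MappingLibraryEntry("hyperbola", lambda x: 2.0 * x / (0.5 + np.asarray(x, float)),
                            {"v": 2.0, "K": 0.5}, (0.0, 10.0)),
        MappingLibraryEntry("hyperbola_mild", lambda x: 1.2 * x / (2.0 + np.asarray(x, float)),
                            {"v": 1.2, "K": 2.0}, (0.0, 10.0)),
        MappingLibraryEntry("exp_saturation",
                            lambda x: 1.5 * (1.0 - np.exp(-np.asarray(x, float) / 0.4)),
                            {"v": 1.5, "tau": 0.4}, (0.0, 10.0)),
        MappingLibraryEntry("sqrt", lambda x: np.asarray(x, float) ** 0.5,
                            {"p": 0.5}, (0.0, 10.0)),
        MappingLibraryEntry("square", lambda x: np.asarray(x, float) ** 2.0,
                            {"p": 2.0}, (0.0, 10.0)),
        MappingLibraryEntry("sigmoid",
                            lambda x: 1.0 / (1.0 + np.exp(-(np.asarray(x, float) - 0.5) / 0.1)),
                            {"midpoint": 0.5, "slope": 0.1}, (0.0, 10.0)),
    ]


# ---------------------------------------------------------------------------
# cascade model (multi-observable analog)
# ---------------------------------------------------------------------------

CASCADE_TRUE = {"k1": 1.0, "k2": 0.4, "k3": 0.15}

#: known decay rate of the stimulus driving the first cascade stage (1/time)
CASCADE_INPUT_DECAY = 0.5


def build_cascade_model() -> ODEModelSpec:
    """Stimulus-driven chain of first-order conversions u(t) -> x1 -> x2 -> x3.

    Three states, three rate parameters, one observable per state — a small
    multi-observable system for experiments with several unknown measurement
    mappings at once.  The chain is driven by a known transient input
    u(t) = exp(-IN_DECAY * t), so every state is a pulse; this keeps the rates
    identifiable through unknown monotone mappings (a strictly monotone
    trajectory, such as free first-order decay, can be reproduced under any
    rate by composing with a power law, and an undriven chain has an exact
    rate-swap symmetry once the per-observable scales are absorbed).
    """
    return ODEModelSpec(
        name="cascade3",
        state_names=("x1", "x2", "x3"),
        parameter_names=("k1", "k2", "k3"),
        rhs_exprs=("exp(-IN_DECAY*t) - k1*x1", "k1*x1 - k2*x2", "k2*x2 - k3*x3"),
        init_exprs=("0", "0", "0"),
        observable_names=("obs_x1", "obs_x2", "obs_x3"),
        observable_exprs=("x1", "x2", "x3"),
        lower_bounds=(-2.0, -2.0, -2.0),
        upper_bounds=(1.0, 1.0, 1.0),
        scales=("log10", "log10", "log10"),
        constants=(("IN_DECAY", CASCADE_INPUT_DECAY),),
    )


def cascade_true_mappings() -> dict[str, Callable]:
    """One origin-through monotone nonlinear mapping per cascade observable.

    All three are saturating curves of distinct curvature with finite slope at
    the origin, matching the assumptions of the origin-anchored
    piecewise-linear spline class (a root law has unbounded slope at zero and
    a convex law pushes its low range below the noise floor; both are known
    hard cases, discussed in the package documentation).
    """
    lib = {e.name: e.func for e in mapping_library()}
    return {"obs_x1": lib["hyperbola"], "obs_x2": lib["exp_saturation"],
            "obs_x3": lib["hyperbola_mild"]}


def cascade_times(n_times: int = 16) -> np.ndarray:
    return np.linspace(0.4, 12.0, n_times)


#: noise SDs ~3% of each observable's mapped dynamic range
CASCADE_SIGMAS = {"obs_x1": 0.03, "obs_x2": 0.04, "obs_x3": 0.015}


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A generated measurement set together with its ground truth."""

    data: MeasurementSet
    theta_true: np.ndarray                  # estimation scale
    mappings: dict[str, Callable]
    sigmas: dict[str, float]
    times: np.ndarray
    seed: int
    model_name: str


def generate_dataset(spec: ODEModelSpec, theta_true, times,
                     mappings: Mapping[str, Callable],
                     sigmas: Mapping[str, float], seed: int,
                     record_noise: bool = True) -> SyntheticDataset:
    """Simulate at the truth, apply each observable's monotone mapping, add noise.

    Noise is i.i.d. Gaussian on the mapped (measurement) scale, drawn from a
    generator seeded with ``seed`` so datasets are exactly reproducible.  With
    ``record_noise`` the generating SD is written into the measurement table's
    noiseValue column, as published benchmark tables do; pass False to emulate
    a dataset whose noise level must be estimated.
    """
    for oid, s in sigmas.items():
        if s <= 0:
            raise ValueError(f"noise SD for {oid!r} must be positive")
    times = np.asarray(times, float)
    sim = simulate(spec, theta_true, times)
    if not sim.success:
        raise RuntimeError(f"simulation at the true parameters failed: {sim.message}")
    rng = np.random.default_rng(seed)
    data = MeasurementSet()
    for i, oid in enumerate(spec.observable_names):
        if oid not in mappings:
            continue
        try:
            mapped = np.asarray(mappings[oid](sim.observables[i]), float)
        except ValueError as err:
            raise RuntimeError(f"mapping domain violation for {oid!r}: {err}") from err
        noisy = mapped + rng.normal(0.0, sigmas[oid], size=mapped.size)
        for t, z in zip(times, noisy):
            data.add(oid, t, z, sigmas[oid] if record_noise else None)
    return SyntheticDataset(data=data, theta_true=np.asarray(theta_true, float),
                            mappings=dict(mappings), sigmas=dict(sigmas),
                            times=times, seed=seed, model_name=spec.name)


# ---------------------------------------------------------------------------
# ready-made problems
# ---------------------------------------------------------------------------

def make_t1_problem(seed: int = 0, truth: FretTruth = FRET_TRUE, n_times: int = 12,
                    n_knots: int = 10, regularization: float = 25.0,
                    record_noise: bool = True,
                    ) -> tuple[ODEModelSpec, SyntheticDataset, list[ObservableConfig]]:
    """The default T1 workflow: model, one seeded dataset, spline observable config.

    The default spline uses 6 knots for the 12-point series (two points per
    increment) and reads the noise SD from the measurement table, matching
    what a characterized benchmark dataset provides; pass
    ``record_noise=False`` to estimate the noise level instead.
    """
    spec = build_fret_model(truth.ptot, truth.stimulus_decay)
    theta_true = truth.theta_scaled(spec)
    dataset = generate_dataset(
        spec, theta_true, t1_times(n_times),
        mappings={"frac_active": t1_true_mapping(truth)},
        sigmas={"frac_active": truth.sigma}, seed=seed, record_noise=record_noise)
    configs = [ObservableConfig(
        "frac_active", mapping_class="nonlinear_monotone", noise_mode="estimate_single",
        n_knots=n_knots, regularization=RegularizationConfig(regularization))]
    return spec, dataset, configs


def make_cascade_problem(seed: int = 0, n_times: int = 16, n_knots: int = 8,
                         regularization: Mapping[str, float] | None = None,
                         ) -> tuple[ODEModelSpec, SyntheticDataset, list[ObservableConfig]]:
    """The 3-observable cascade with a different nonlinear mapping per observable.

    Regularization strengths default to the scale-matched rule lam = 0.01/sigma^2
    per observable, weighting the linearity prior like the data.
    """
    spec = build_cascade_model()
    theta_true = spec.to_scaled(np.array([CASCADE_TRUE[k] for k in spec.parameter_names]))
    dataset = generate_dataset(spec, theta_true, cascade_times(n_times),
                               mappings=cascade_true_mappings(),
                               sigmas=dict(CASCADE_SIGMAS), seed=seed)
    if regularization is None:
        regularization = {oid: 0.01 / s**2 for oid, s in CASCADE_SIGMAS.items()}
    configs = [ObservableConfig(
        oid, mapping_class="nonlinear_monotone", noise_mode="estimate_single",
        n_knots=n_knots, regularization=RegularizationConfig(regularization[oid]))
        for oid in spec.observable_names]
    return spec, dataset, configs
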