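"""Readers and writers for model, measurement and result files.

Formats: YAML for model definitions and run configuration, PEtab-style TSV
for measurement and observable tables, TSV for fitted mappings and
credibility bands, CSV for trajectories and MCMC chains, JSON for fit
reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimate import FitResult, SampleResult
from .inner import InnerSolution, MeasurementSet, ObservableConfig
from .models import ODEModelSpec
from .spline import RegularizationConfig, SplineMapping

__all__ = [
    "read_model",
    "write_model",
    "read_measurements",
    "write_measurements",
    "read_observable_configs",
    "write_observable_configs",
    "write_mapping_tsv",
    "read_mapping_tsv",
    "write_fit_report",
    "write_chain_csv",
    "write_bands_tsv",
]


# ---------------------------------------------------------------------------
# model YAML
# ---------------------------------------------------------------------------

def read_model(path) -> ODEModelSpec:
    """Load a model definition from its YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        states = list(raw["states"])
        params = raw["parameters"]
        odes = raw["odes"]
        initial = raw["initial"]
        observables = raw["observables"]
    except (KeyError, TypeError) as err:
        raise ValueError(f"model file {path} is missing section {err}") from err
    names = list(params)
    return ODEModelSpec(
        name=str(raw.get("name", Path(path).stem)),
        state_names=tuple(states),
        parameter_names=tuple(names),
        rhs_exprs=tuple(str(odes[s]) for s in states),
        init_exprs=tuple(str(initial[s]) for s in states),
        observable_names=tuple(observables),
        observable_exprs=tuple(str(e) for e in observables.values()),
        lower_bounds=tuple(float(params[n]["lower"]) for n in names),
        upper_bounds=tuple(float(params[n]["upper"]) for n in names),
        scales=tuple(str(params[n].get("scale", "log10")) for n in names),
        constants=tuple((str(k), float(v)) for k, v in (raw.get("constants") or {}).items()),
        t0=float(raw.get("t0", 0.0)),
    )


def write_model(spec: ODEModelSpec, path) -> None:
    doc = {
        "name": spec.name,
        "states": list(spec.state_names),
        "parameters": {
            n: {"lower": float(lo), "upper": float(up), "scale": s}
            for n, lo, up, s in zip(spec.parameter_names, spec.lower_bounds,
                                    spec.upper_bounds, spec.scales)
        },
        "constants": {k: float(v) for k, v in spec.constants},
        "odes": dict(zip(spec.state_names, spec.rhs_exprs)),
        "initial": dict(zip(spec.state_names, spec.init_exprs)),
        "observables": dict(zip(spec.observable_names, spec.observable_exprs)),
        "t0": spec.t0,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# measurement table (PEtab-style TSV)
# ---------------------------------------------------------------------------

def read_measurements(path, observable_ids=None) -> MeasurementSet:
    """Parse a PEtab-style measurement table (observableId, time, measurement[, noiseValue])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("observableId", "time", "measurement"):
        if col not in df.columns:
            raise ValueError(f"measurement table {path} is missing column {col!r}")
    if df.empty:
        import warnings
        warnings.warn(f"measurement table {path} contains no rows", stacklevel=2)
    data = MeasurementSet()
    has_noise = "noiseValue" in df.columns
    for row_no, row in df.iterrows():
        oid = str(row["observableId"])
        if observable_ids is not None and oid not in observable_ids:
            raise ValueError(f"row {row_no}: unknown observable {oid!r}")
        for col in ("time", "measurement"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"row {row_no}, column {col!r}: non-numeric value {row[col]!r}")
        sigma = float(row["noiseValue"]) if has_noise and pd.notna(row["noiseValue"]) else None
        data.add(oid, float(row["time"]), float(row["measurement"]), sigma)
    return data


def write_measurements(data: MeasurementSet, path) -> None:
    data.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# observable configuration table
# ---------------------------------------------------------------------------

def read_observable_configs(path) -> list[ObservableConfig]:
    df = pd.read_csv(path, sep="\t")
    if "observableId" not in df.columns or "mappingClass" not in df.columns:
        raise ValueError(f"observable table {path} needs observableId and mappingClass columns")
    configs = []
    for _, row in df.iterrows():
        known = row.get("noiseValue")
        kwargs = dict(
            observable_id=str(row["observableId"]),
            mapping_class=str(row["mappingClass"]),
            noise_mode=str(row.get("noiseMode", "estimate_single")),
            known_sigma=float(known) if pd.notna(known) else None,
        )
        if pd.notna(row.get("nKnots")):
            kwargs["n_knots"] = int(row["nKnots"])
        if pd.notna(row.get("margin")):
            kwargs["margin"] = float(row["margin"])
        if pd.notna(row.get("regularizationStrength")):
            kwargs["regularization"] = RegularizationConfig(float(row["regularizationStrength"]))
        configs.append(ObservableConfig(**kwargs))
    return configs


def write_observable_configs(configs, path) -> None:
    rows = [{
        "observableId": c.observable_id,
        "mappingClass": c.mapping_class,
        "noiseMode": c.noise_mode,
        "noiseValue": np.nan if c.known_sigma is None else c.known_sigma,
        "nKnots": c.n_knots,
        "margin": c.margin,
        "regularizationStrength": c.regularization.effective_strength,
    } for c in configs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fitted mappings, reports, chains, bands
# ---------------------------------------------------------------------------

def write_mapping_tsv(mapping: SplineMapping, path) -> None:
    pd.DataFrame({"knot_base": mapping.knots,
                  "knot_height": mapping.knot_heights}).to_csv(path, sep="\t", index=False)


def read_mapping_tsv(path) -> SplineMapping:
    df = pd.read_csv(path, sep="\t")
    heights = df["knot_height"].to_numpy(float)
    return SplineMapping(df["knot_base"].to_numpy(float),
                         np.diff(np.concatenate([[0.0], heights])))


def _mapping_json(sol: InnerSolution) -> dict:
    out = {"mapping_class": sol.mapping_class,
           "sigma": float(sol.sigma[0]) if np.ptp(sol.sigma) == 0 else sol.sigma.tolist(),
           "objective": sol.objective}
    if sol.mapping_class == "relative":
        out.update(sol.parameters)
    elif sol.mapping is not None:
        out["knot_base"] = sol.mapping.knots.tolist()
        out["knot_height"] = sol.mapping.knot_heights.tolist()
    return out


def write_fit_report(fit: FitResult, path, inner: dict[str, InnerSolution] | None = None,
                     settings: dict | None = None, parameter_names=None) -> None:
    report = {
        "theta_star": fit.theta_star.tolist(),
        "value_star": fit.value_star,
        "seed": fit.seed,
        "mode": fit.mode,
        "n_starts": fit.n_starts,
        "parameter_names": list(parameter_names) if parameter_names else None,
        "settings": settings or {},
        "starts": [{
            "theta0": s.theta0.tolist(), "theta": s.theta.tolist(),
            "value": None if not np.isfinite(s.value) else s.value,
            "grad_norm": None if not np.isfinite(s.grad_norm) else s.grad_norm,
            "n_evaluations": s.n_evaluations, "n_iterations": s.n_iterations,
            "success": s.success,
        } for s in fit.starts],
    }
    if fit.converged is not None:
        report["converged"] = fit.converged.tolist()
    if inner:
        report["mappings"] = {oid: _mapping_json(sol) for oid, sol in inner.items()}
    Path(path).write_text(json.dumps(report, indent=2))


def write_chain_csv(sample: SampleResult, path) -> None:
    cols = list(sample.parameter_names) or [f"theta_{j}" for j in range(sample.chain.shape[1])]
    df = pd.DataFrame(sample.chain, columns=cols)
    df["log_posterior"] = sample.log_posterior
    df.to_csv(path, index=False)


def write_bands_tsv(sample: SampleResult, observable_id: str, path) -> None:
    band = sample.bands[observable_id]
    pd.DataFrame({"x": band["grid"], "lower": band["lower"], "upper": band["upper"],
                  "level": band["level"]}).to_csv(path, sep="\t", index=False)
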