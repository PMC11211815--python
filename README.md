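# semiquant

Maximum-likelihood parameter estimation for ODE models when some observables
are measured through an **unknown monotone nonlinear transformation** —
so-called semi-quantitative data (FRET ratiometric imaging, optical density,
staining intensities, …).

The package is for modelers in systems biology who need to calibrate a
mechanistic model `dx/dt = f(x, θ, t)`, `y = h(x, θ)` against measurements

```
z̃_ik = g_i(y_i(t_k, θ)) + ε_ik,   ε_ik ~ N(0, σ_ik²),
```

where each measurement mapping `g_i` may be known only up to monotonicity.
Unknown mappings are reconstructed with a **monotone piecewise-linear spline**
parameterized by nonnegative height increments ξ on an origin-anchored
uniform knot grid,

```
s(x, ξ) = (x − c_{j−1})/Δc · ξ_j + Σ_{l<j} ξ_l    for c_{j−1} ≤ x ≤ c_j,
```

plus a linearity-promoting penalty `(λ/2) Σ_j (ξ_j − ξ̄)²`. Estimation is
**hierarchical**: the outer problem minimizes the negative log-likelihood
`J(θ, ψ*(θ))` over the mechanistic parameters θ, while per observable the
mapping/noise parameters ψ_i are profiled out exactly — closed-form weighted
least squares for affine ("relative") observables, a convex
nonnegativity-constrained least-squares problem (solved by NNLS on a
Tikhonov-augmented system) for spline observables, and the MLE
`σ*² = mean(residual²)` for unknown noise. Because ψ*(θ) is an inner optimum,
inner parameters contribute no first-order terms and the outer gradient is
analytic,

```
∇_θ J = Σ_{i,k} (m_ik − z̃_ik)/σ_i² · g_i′(y_ik) · ∂y_ik/∂θ ,
```

with `∂y/∂θ` from forward-sensitivity integration of the augmented ODE
system. On top of this the package provides multi-start optimization with
Latin-hypercube starts, likelihood-ratio confidence regions
`{θ : 2(J(θ) − J(θ*)) ≤ χ²_{nθ}(α)}`, adaptive Metropolis sampling with
per-sample profiled splines and pointwise credibility bands for the
reconstructed mappings, a mapping-shape classifier
(quantitative / relative / censored-like / nonlinear), and fully synthetic
benchmark generators (a stimulus-driven FRET probe-activation model and a
three-observable cascade) so every experiment runs without downloads.

## Worked example

`examples/fit_semiquantitative.py` generates one noisy FRET dataset
(12 time points, noise SD 0.02 on the measured ratio) and fits it with the
mapping treated as unknown:

```
best negative log-likelihood J* = -35.647
converged starts (within the 95% confidence region): 15/20
   parameter   estimate      truth   (log10 scale for rates)
       k_act     -0.615     -0.523
     k_deact     -1.070     -1.097

likelihood-ratio statistic at the truth: 0.16 (95% threshold 9.49)

 input y  spline s(y)  true g(y)
   0.035        0.060      0.036
   0.108        0.160      0.121
   0.181        0.295      0.222
   0.255        0.419      0.342
   0.328        0.652      0.489
   0.402        0.877      0.671
```

Both rate constants are recovered to within a factor ≈1.2 (0.09 and 0.03 on
the log10 scale), the generating parameters lie deep inside the 95%
likelihood-ratio confidence region (Λ = 0.16 against a threshold of 9.49),
and the profiled spline tracks the generating ratiometric calibration over
the data-covered range while remaining somewhat steeper at the top, where a
12-point dataset leaves the mapping soft. The other examples demonstrate
simulation with sensitivities (`simulate_fret.py`), credibility bands for
mappings on the multi-observable cascade (`credibility_bands.py`), and the
data-triage classifier (`classify_mapping_shapes.py`).

A thin CLI mirrors the library for shell use:

```bash
semiquant fixtures --model t1 --seed 1 --out fx/
semiquant fit --model fx/model.yaml --measurements fx/measurements.tsv \
              --observables fx/observables.tsv --n-starts 20 --seed 2 --out fit/
semiquant report --fit-dir fit/ --out plots/
```

Models are plain YAML (states, parameters with bounds/scales, ODEs, initial
conditions, observables); measurements and observable configurations are
PEtab-style TSV tables.

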