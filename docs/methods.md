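# Methods

This note documents the statistical model, the numerical choices, the bundled
synthetic benchmarks, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and likelihood

A model is an ODE system `dx/dt = f(x, θ, t)`, `x(t0) = x0(θ)` with
observables `y = h(x, θ)`. Kinetic parameters are estimated on the log10
scale by default (bounds are declared on the estimation scale per parameter);
linear scale is available for parameters that may be negative. Measurements
attach to observables in one of three classes:

* **quantitative** — identity mapping, only the noise SD may be unknown;
* **relative** — affine mapping `g(y) = a·y + b` with unknown scale/offset;
* **nonlinear-monotone** — the mapping is an unknown monotone function,
  approximated by a piecewise-linear spline.

Noise is additive Gaussian **on the measurement scale** (after the mapping),
either known per data point (the `noiseValue` column of the measurement
table) or a single estimated SD per observable. Per-time-point noise is never
estimated (unidentifiable).

The negative log-likelihood separates additively over observables,
`J(θ, ψ) = Σ_i J_i(θ, ψ_i)`, where ψ_i collects observable parameters
((a, b), spline increments ξ, and/or σ). Estimation is hierarchical: for
every outer candidate θ the inner problems `ψ_i*(θ) = argmin J_i` are solved
exactly, and the outer optimizer sees `J(θ, ψ*(θ))`.

## Spline mapping

The spline is parameterized by height increments ξ_j ≥ 0 on a uniform,
origin-anchored knot grid `c_j = j·Δc`; knot heights are cumulative sums, so
monotonicity is a bound constraint rather than a general inequality. The
final branch extrapolates at the constant total height — the only
continuation that preserves both continuity and monotonicity. The derivative
uses the right-interval slope at interior knots (half-open interval
convention) and is zero beyond the last knot.

Two consequences of the origin anchor are assumptions about the data:

* **mappings pass through the origin** — s(0) = 0 always. Measurements with a
  baseline offset (e.g. un-subtracted background fluorescence) must be
  background-corrected first; otherwise the fit is biased, because the offset
  must be absorbed into the first knot interval.
* **finite slope at zero** — a root-law mapping (x^p, p < 1) has unbounded
  slope at the origin and cannot be tracked there by any linear-through-origin
  first segment.

By default the knot grid is rebuilt from the current simulation at every
outer evaluation (`make_knot_grid`, margin 0.3, so the grid spans
[0, 1.3·max(y)]). This guarantees coverage of the simulated range but makes
the outer objective mildly non-smooth where the grid changes; a fixed-grid
mode (`HierarchicalObjective.with_grids`/`freeze_grids`) provides a strictly
smooth objective and is used for gradient verification and for comparisons
against the joint formulation.

### Regularization

The penalty `(λ/2) Σ_j (ξ_j − ξ̄)²` is zero exactly when the spline is
globally linear; it both regularizes the underdetermined directions of ξ and
suppresses staircase-shaped splines (alternating zero/large increments) that
otherwise overfit single noise realizations. The library default is
λ = 10⁻², but λ carries units of 1/measurement² and a fixed value cannot be
right on every scale: the bundled study problems use the scale-matched rule
**λ = 0.01/σ²**, which weights the linearity prior like the data
irrespective of the measurement units. Users should expect to set λ relative
to their noise level; with λ far below 1/σ² the penalty is inert, far above
it the mapping is forced affine.

A practical note on strong regularization and uncertainty: because the
penalty biases *every* profiled spline the same way, oversized λ narrows the
spread of per-sample splines without removing the shared bias — credibility
bands then undercover. The cascade benchmark therefore uses the 0.01/σ² rule,
not more.

## Inner solvers

* **Relative observables**: weighted ordinary least squares in closed form;
  with a single estimated σ the weights drop out and σ*² is the mean squared
  residual (the Gaussian MLE). Degenerate simulations (zero variance in y)
  are flagged non-identifiable and return a = 0, b = weighted mean.
* **Spline observables**: the inner problem
  `min_{ξ≥0} (1/2σ²)‖z − Bξ‖² + (λ/2)‖ξ − ξ̄‖²` is a convex quadratic
  program. It is solved as plain NNLS on the weighted design stacked with
  `sqrt(λ_eff)·M`, where `M = I − (1/n)11ᵀ` is the mean-centering projector
  (idempotent, so `ξᵀMξ = ‖Mξ‖²`). With estimated σ and λ > 0 the two couple;
  a fixed-point pass (solve ξ at the current σ, update σ from the residuals,
  re-solve) is iterated at most 10 times or to 1e-10 relative change in J_i —
  it preserves per-step convexity and in practice converges in 2–3 passes.
* Estimated noise SDs are floored at 1e-10 so the log-likelihood stays finite
  on perfectly fit data.

## Outer gradient

Forward sensitivities are integrated with the augmented system
`dS/dt = (∂f/∂x)S + ∂f/∂θ`, `S(t0) = ∂x0/∂θ` (all Jacobians generated
symbolically once per model via sympy) and chained through the observation
map; log10-scale parameters get the chain factor `ln(10)·θ_lin`. At the inner
optimum the envelope/KKT argument removes all ψ-terms, leaving
`∇_θJ = Σ (m − z̃)/σ² · g′(y) · ∂y/∂θ`. With a frozen knot grid this gradient
matches central finite differences of the full hierarchical map to ~1e-6
relative (the verification re-solves the inner problems at every perturbed
θ). Two numerical caveats: finite-difference checks need integrator
tolerances well below the FD step (the tests use rtol 1e-11/atol 1e-13
against steps of 1e-5; the library default rtol 1e-8/atol 1e-10 with a
stiff-capable LSODA integrator is for production fitting), and under adaptive
re-gridding the analytic gradient treats the grid as frozen — the induced
error is an accepted outer-loop effect since the grid stabilizes near optima.

Integrations that diverge (non-finite or > 1e12 state magnitude) are aborted
and reported through a success flag; the objective maps them to +∞, so
multi-start runs survive pathological parameter draws.

## Optimization

Multi-start local optimization from Latin-hypercube draws over the bounded
(log10) box. Gradient mode uses bounded L-BFGS-B consuming the fused
value+gradient evaluation, with two robustness choices for the mildly
non-smooth adaptive-grid objective: a long line search (`maxls = 50`) and up
to three fresh-memory restarts whenever the relative-reduction test fires
while the run is still improving (a kink can trigger that test far from any
stationary point). The gradient-free baseline is SciPy's Powell direction-set
method on the same hierarchical objective. The joint (non-hierarchical)
formulation stacks θ with all ψ blocks — bounds ξ ≥ 0, free (a, b) — and
profiles σ analytically in both formulations so their objectives are directly
comparable; at ψ = ψ*(θ) they agree to integrator tolerance.

Convergence of a start is judged by the likelihood-ratio statistic
`Λ = 2(J − J*) ≤ χ²_{nθ}(0.95)` against the best found optimum, following
standard multi-start practice; the sorted final objectives (waterfall) are
the visual diagnostic.

## Sampling and credibility bands

The posterior over θ is the hierarchical likelihood under a uniform prior on
the bounded box (observable and noise parameters are profiled, not sampled).
The sampler is adaptive Metropolis: proposal covariance `2.38²/d` times the
running chain covariance (epsilon-regularized), adapted every 25 iterations
during the first 20% of the chain and frozen afterwards to preserve
asymptotic correctness. For each retained sample the inner problems are
re-solved, and per-observable credibility bands are central percentile
envelopes of the per-sample optimal splines over a fixed grid spanning
[0, median over samples of the largest simulated value at a data time] — the
data-informed input range.

These are **profile bands**: they carry parameter uncertainty only, not the
sampling error of the inner spline estimate itself. Where the mapping is
precision-limited by measurement noise rather than by θ (e.g. a mapping whose
low range sits below the noise floor), the bands can sit off the truth by a
noise-scale amount over a contiguous region. This is inherent to the
per-sample-optimal-spline construction, not to chain length.

## Synthetic benchmarks

The generators define the study conditions; they emulate noisy time-course
data pushed through monotone calibration curves, with the generating SD
recorded in the measurement table (as characterized benchmark datasets
provide). They do not emulate biological replicates, dosing/condition
structure, non-Gaussian noise, or missing data — passing tests show method
correctness under the stated conditions, not robustness to those features.

**T1 (FRET probe activation).** Two states (inactive P, active P*) with
conservation P + P* = PTOT = 10; the forward enzyme is a transient stimulus
`k_act·exp(−0.25 t)` with the decay rate treated as a known, experimentally
characterized input, and deactivation is first order (k_deact). True rates
k_act = 0.3, k_deact = 0.08 /min give an activation pulse peaking near
t ≈ 5.5 min (active fraction ≈ 0.47). The pulse matters: a strictly monotone
trajectory can be reproduced under *any* rate pair by bending the monotone
mapping (the profile likelihood is exactly flat along a 2-d manifold), so a
constant-drive variant (`stimulus_decay=0`, kept for closed-form tests) has
no recoverable mapping. The observable y = P*/PTOT is measured by ratiometric
imaging, `g(P*) = α·P*/(PTOT − P*) + β`, with α = 1 and β = 0 (ratios are
assumed background-corrected; the origin-anchored spline cannot represent a
baseline offset). Twelve log-spaced time points on [0.5, 40] min, noise SD
0.02 (≈2% of the mapped dynamic range, high-quality imaging). Rate bounds
log10 ∈ [−2, 1]: rates outside [10⁻², 10¹]/min are unobservable in a
0.5–40 min design. The spline uses nξ = 10 knots — the top of the practical
5–10 band — so that the piecewise-linear approximation error of the convex
calibration (≈0.006 on the measurement scale) stays below the noise floor;
with coarser grids the approximation error is itself a noise-scale
misspecification and distorts the likelihood-ratio calibration. α and β are
carried as estimable parameters of the parametric-mapping variant; in the
spline workflow they are flat directions (their gradient components are
exactly zero) and the χ² threshold with df = 4 is correspondingly
conservative.

**Cascade.** Three states driven by a known transient input
`u(t) = exp(−0.5 t)` through first-order conversions (k1 = 1.0, k2 = 0.4,
k3 = 0.15), one observable per state, 16 equispaced times on [0.4, 12]. The
known input breaks two degeneracies of an undriven chain: the exact k1↔k2
swap symmetry (which leaves the third state invariant once per-observable
scales are absorbed) and the power-law absorption of the rate of a pure
exponential decay. The three generating mappings are saturating curves of
distinct curvature — hyperbola v·x/(K+x) with K = 0.5, exponential saturation
v·(1−e^(−x/τ)), and a mild hyperbola with K = 2 — all with finite slope at
the origin; noise SDs (0.03, 0.04, 0.015) are ≈3% of each observable's mapped
range. The mapping library additionally ships identity, affine, square,
square-root and sigmoid entries; the root law (infinite slope at 0), the
convex square (low range below the noise floor) and mappings with offsets are
deliberately *not* used as defaults — they violate the spline class
assumptions above and are useful precisely as documented hard cases.

## Problem sizes used by the acceptance script

Gradient check: 10 random bounded parameter vectors, FD step 1e-5, frozen
grids. Inner-solver oracle: 3 knots × 5 points, grid search at step 0.05 plus
local polish. Mapping recovery: 50 starts, closest converged spline to the
generating calibration in sup-norm over the intersection of data-covered
input ranges (the Fig-3B-style selection), reported in units of σ.
Confidence-region coverage: 20 replicate datasets × 20 starts, χ²₄ threshold
at 95%. Credibility bands: 10⁴ adaptive-Metropolis iterations thinned by 50
(200 retained samples; a ten-fold longer chain gives the same coverage).
Joint/hierarchical equivalence: 10 shared starts at tight tolerances plus
cross-initialization of the joint problem from the hierarchical optimum.
Efficiency: 10 informative starts (outside the 95% region), paired
first-passage counts of objective evaluations, gradient vs Powell.

## Known limitations

* Mapping recovery as a *point estimate* is soft at small data sets: on the
  12-point T1 benchmark the profiled mapping can move by several σ in
  sup-norm along likelihood ridges that change J by well under one nat, so
  the closest-converged-start deviation fluctuates across noise realizations
  (and with 50 starts the confidence region is populated sparsely). Parameter
  coverage is unaffected; mapping uncertainty should be read from the
  credibility bands, not from a single profiled spline.
* Profile credibility bands exclude inner-estimation uncertainty (above).
* The origin anchor excludes offsets and infinite-slope-at-zero mappings by
  construction.
* No events/dosing, steady-state pre-equilibration, SBML import, adjoint
  sensitivities, second-order derivatives, or smooth spline families; noise
  is Gaussian only, and censoring is a classification outcome, not a
  likelihood.
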