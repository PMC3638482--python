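# Methods

## Model class

`adaptkit` works with kinetic network models

    dx/dt = N f(x, θ, u) + B u,      y = C x,

where `x` are species concentrations (arbitrary units), `N` the integer
stoichiometric matrix, `f` non-negative irreversible rate laws, `B` routes
constant (or pulsed) input fluxes into the balances, and `C` is a 0/1
selection matrix. Conserved moieties (left null vectors of `[N | B]`) are
detected numerically by SVD; they are *verified*, never eliminated
analytically, which keeps the model abstraction generic. Simulation uses
`scipy.integrate.solve_ivp` with LSODA and absolute/relative tolerances of
1e-6 by default (configurable); the systems of interest are stiff because
gene-circuit rate constants sit three or more orders of magnitude below
the metabolic ones.

Steady states are solved by a damped Newton iteration on the balance
equations augmented with one pinning equation per conserved moiety (the
totals implied by the initial guess), with backtracking line search,
positivity clipping and a long-horizon-integration fallback. The fallback
doubles as an independent oracle in the tests. Failure raises an error
carrying the residual norm; negative solutions are rejected.

Parameter variances for classical per-stage fits are approximated from
the inverse Fisher information of the weighted least-squares problem,
`diag((Jᵀ W J)⁻¹)` with `W = diag(1/σ²)` and `J = ∂y_ss/∂θ` by central
finite differences with relative step 1e-6. The steady states inside the
difference stencil are solved to 1e-10 so the differencing noise stays
well below the sensitivity signal. A condition number above 1e14 is
reported as structural non-identifiability (e.g. jointly freeing the
transcription and degradation constants, which enter the steady state
only through their ratio).

## Data interpolants

Snapshot data are per-stage means `d` and standard deviations `σ` of each
observable. Continuous descriptions are cubic smoothing splines in the
weight convention `p ∈ (0, 1]`:

    minimize  p Σ_i (d_i − s(t_i))² + (1 − p) ∫ s''(t)² dt,

so `p = 1` interpolates and `p → 0` approaches the ordinary least-squares
line. The minimizer is computed directly as the natural cubic spline
through the shrunk values `g = (I + λK)⁻¹ d`, `λ = (1−p)/p`, with `K` the
standard curvature matrix of Green & Silverman's formulation. This
direct construction works from two data points up (the library penalized
spline requires five) and agrees with `scipy.interpolate
.make_smoothing_spline` to machine precision where both are defined; that
agreement is asserted in the test suite. The default weight is the
spacing heuristic `p = 1/(1 + h³/6)` with `h` the mean stage spacing
(`p = 6/7` for daily stages); it is fixed once per dataset, not refit per
bootstrap replicate (configurable).

Bootstrap replicates are parametric: means redrawn elementwise from
`Normal(d, σ)`, SDs kept. Negative draws are retained — the error model
is unconditionally Gaussian, and truncation would bias the replicate
moments the tests check. An ensemble of `n` replicate splines forms the
interpolant distribution; 2-D density histograms (left-closed/right-open
bins, last bin closed) summarize curve ensembles.

Between stages `σ(t)` is interpolated linearly. It is floored at
`ε_j = 0.01 · max(max_t |d_tj|, 1)` per observable: weights in the data
misfit are capped at what a ~1% assay precision would justify. Without a
floor the objective is undefined wherever a drawn σ is zero; with a
much smaller floor, near-zero draws (which the uniform σ model produces
regularly) would dominate the fit with weights no real measurement could
support, and noise-free datasets would amplify the irreducible
spline-versus-model mismatch into astronomically large SSE values. The
floor is configurable (`sigma_floor_rel`).

## The step-wise estimator

Within one slow step `[t, t+δt]` the model is integrated for a fixed
fast-time horizon (default 1e4 fast units) from the current state with
candidate parameters held constant; the fixture's rate constants
guarantee metabolic relaxation well inside that horizon, so the state
tracks the quasi-steady manifold of the current parameters. The free
parameters minimize `X_d + λ_r X_r` at the step endpoint only, via
`scipy.optimize.least_squares` (Levenberg–Marquardt) on the stacked
residual vector `[(y−d)/σ/√N ; √(λ_r/M) Δθ/(θ_ref δt)]`, in
log-parameter space (positivity is structural), warm-started at `θ̂(t)`,
with termination tolerances 1e-6. Simulation failures inside the
optimizer return a large finite residual (1e6) and are recorded; the
candidate is thereby penalized, not fatal.

Choices that were genuinely open, and what this package does:

* **Roughness normalizer** `θ_ref`: the step-start value `θ̂(t)`
  (per-step normalization), making the penalty scale-invariant; the
  forward difference over `δt` approximates the derivative. The
  trajectory-start normalizer is a one-line change in `objective_reg`
  callers if a fixed reference is preferred.
* **Averaging**: `X_d` carries `1/N`, `X_r` carries `1/M`. The acceptance
  statistic compares the *un-averaged* cumulative SSE `Σ_steps X_d·N`
  against `sseThres` (default 1000), accumulated against the replicate's
  own interpolant; a config switch (`sse_statistic="data"`) scores
  against the raw stage data instead.
* **Initialization**: free parameters drawn log-uniformly on
  `[lr·θ_ref, ur·θ_ref]` (defaults 0.1, 10), then fitted to the
  interpolant at `t0` by `X_d` alone with the model at steady state.
  Steady-state failures trigger up to five re-draws. The median of the
  log-uniform draw is the geometric mean of the bounds (= θ_ref for the
  default symmetric bounds).
* **Multimodality** is probed across replicates through these random
  starts, not by basin hopping within a replicate.
* **Reproducibility**: each replicate's generator is spawned from the
  single configured seed (`numpy.random.SeedSequence`), so ensembles are
  bit-identical under reruns and independent of execution order.

Defaults: `λ_r = 0.1`, `δt = 0.1`, `nr = 1000`, `sseThres = 1000`.

## Pareto trade-off

`lambda_sweep` traces mean total `X_d` and `X_r` across a fixed-seed
ensemble per `λ_r`. Across the full range (from 0 to the freezing regime
around 1e6) misfit rises and roughness falls monotonically. In a middle
band (`λ_r ≈ 1–10` on the case study) realized roughness can locally
*exceed* the unregularized value: the penalty delays parameter movement
until the accumulating data error forces a compressed "catch-up", and a
burst of movement is rougher than the same movement spread evenly. Sweep
grids should therefore span the front rather than sample only the
transition band.

## The case-study fixture

The topology and default parameters are package fixtures, constructed in
one place (`case_study`) so they can be swapped wholesale: Vmax=1,
Ki=0.1, k2=1, k3=0.1, k4=0.5, k5=0.2, kd=2e-4, u1=1, u2=0.2 (fast time in
seconds), reference k6=0.01 declining ×0.5 per stage over five daily
stages. They were chosen so that (i) the metabolic subsystem relaxes
within ~10 s after a small input pulse, (ii) the gene circuit is ≥1e3×
slower than metabolism, (iii) every stage has a positive steady state,
and (iv) relieving the inhibition strictly increases the reaction-1 flux
across stages. The second input `u2` feeds S4; the inhibition law is the
single-site form `1/(1 + R1/Ki)`; transcription is `k6·S4`. The lumping
identity `k1 = Vmax/(1 + R1_ss/Ki)` makes the reduced four-state model's
metabolite steady state coincide exactly with the true system's, which is
what "truth-implied k1" means in the recovery tests.

## Synthetic data

The generator emulates staged steady-state phenotyping: per stage, solve
the steady state, observe through `C`, add Gaussian noise with SD drawn
uniformly on `[0, max_rel_sd ·  y_ref]` (reference-stage output scaling,
default 20%). SDs are drawn per stage by default; a flag shares one draw
across stages. What the generator does *not* emulate: longitudinal
correlation of errors, non-Gaussian tails, systematic assay bias,
off-steady-state sampling, or missing observables. Passing recovery tests
therefore demonstrates correctness of the estimator under the stated
error model, not robustness to real-world measurement pathologies.

## Problem sizes used in the shipped checks

The end-to-end checks run scaled-down ensembles chosen to exercise every
code path at desk scale: nr = 50 replicates for noise-free trajectory
recovery, nr = 100 for the cross-case coherence comparison, nr = 20 per
point of the Pareto sweep, 500 bootstrap re-estimates against the Fisher
information, and 1e4 replicates for Monte-Carlo moment checks. Production
analyses would use the default nr = 1000.

## Known limitations

* The fast/slow bridging assumes full metabolic relaxation within each
  slow step; systems with metabolic time scales approaching `δt·(time
  conversion)` need a shorter relaxation horizon or explicit fast-time
  alignment.
* The step-endpoint objective ignores the path inside a step; integrated
  residuals are out of scope.
* The Fisher-information variance is asymptotic and local; it is
  validated here against the bootstrap only at desk scale.
* No SBML import, no events, no delays, no analytic Jacobians or adjoint
  sensitivities.
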