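# Methods

## Model and assumptions

The package studies a network of `N = N_E + N_I` graded rate neurons in
two fully homogeneous populations, excitatory and inhibitory, with
all-to-all coupling and no self-connections (in-degree `M = N − 1` by
default).  The membrane potential of neuron `i` obeys

    dV_i/dt = −V_i/τ_i + (1/M_i) Σ_j J_ij 𝒜_j(V_j) + I_i + σ_i^B dB_i/dt.

The activation is the algebraic sigmoid
`𝒜(V) = (ν^max/2)[1 + u/√(1+u²)]` with `u = (Λ/2)(V − V^T)`; its
derivatives are available in closed form (`𝒜′ = (ν^max Λ/4)(1+u²)^{−3/2}`,
maximal at threshold).  Synaptic weights respect Dale-type sign
constraints (`J_EE, J_IE ≥ 0`, `J_EI, J_II ≤ 0`), enforced at
construction: the analytic bifurcation conditions assume these signs, so
violations are errors rather than warnings.

The noise is additive white noise whose `N × N` covariance `Σ^B` has the
homogeneous block structure: within-population blocks
`(σ_α^B)²[Id + C_αα^B(𝟙 − Id)]`, between-population blocks
`σ_E^B σ_I^B C_EI^B 𝟙`.  `Σ^B` is validated as symmetric positive
semidefinite with eigenvalue tolerance `−1e−12 × max diagonal`, which
admits the exactly singular case of perfectly shared noise (`C^B = 1`).

Two assumptions underpin everything downstream:

* **weak noise** — the stationary fluctuation scale stays below the
  minimum curvature radius `r(μ) = |(1+𝒜′²)^{3/2}/𝒜″|` of the activation
  at the operating point, so the first-order (linear response) expansion
  is trusted.  `weak_noise_check` evaluates exactly this criterion.
* **homogeneity** — neurons within a population are exchangeable, so the
  stationary covariance has only five distinct scalars and the Jacobian
  spectrum decomposes into intra- and inter-population parts.

## Stationary covariance

Around a stable equilibrium the linearized network is a set of coupled
Ornstein–Uhlenbeck processes; the stationary covariance solves the
algebraic Lyapunov relation `𝒥 Σ + Σ 𝒥ᵀ + Σ^B = 0`.  Two routes:

* **Lyapunov route** (`lyapunov_covariance`): dense
  `scipy.linalg.solve_continuous_lyapunov` on the full `N × N` system.
  Valid for any number of populations and any stable Jacobian; the
  circuits of interest are small (tens of neurons), so a dense solve is
  exact and cheap.  This is the package's independent oracle.
* **Closed form** (`closed_form_covariance`, two populations): the
  Jacobian eigenvalues split into `λ_α = −(1/τ_α + J_αα 𝒜′_α/M_α)`
  (multiplicity `N_α − 1`) and the collective pair
  `λ^R_{0,1} = (𝒴+𝒵 ± √((𝒴−𝒵)²+4𝒳))/2`, where `𝒴, 𝒵` are the diagonal
  entries of the 2×2 collective matrix and `𝒳` the product of its
  off-diagonal entries.  The five covariance scalars are explicit in
  `λ_E, λ_I, λ^R_{0,1}` and the coupling coefficients `K_{0,1}` through
  ten `Υ` coefficients plus the noise-mixing factors
  `Δ_α = 1/N_α + C_αα^B(1 − 1/N_α)` and `Θ_α = (1 − C_αα^B)/(2λ_α)`.

Numerical choices in the closed form:

* Everything is evaluated in **complex arithmetic** — the collective pair
  is complex conjugate throughout the Hopf neighbourhood and the `Υ`
  expressions remain valid there; the final scalars are cast to real only
  after checking the imaginary residue is below `1e−10` relative.
* `K_x` has two algebraically equivalent forms (dividing by the E→I or
  the I→E pathway); the better-conditioned denominator is used and the
  two forms are cross-checked when both exceed `1e−12`.
* The `Υ` expressions carry `(K_1 − K_0)²` denominators, which degenerate
  in the decoupled/saturated limit.  When `|K_1 − K_0| <
  1e−8 · max(|K_0|, |K_1|, 1)` the implementation falls back silently
  (with a logged notice) to the Lyapunov route; the result is the same to
  solver precision, only the algebraic path differs.
* Covariances only exist at strictly stable equilibria; a spectral
  abscissa above `−1e−12` is rejected.  The genuinely indeterminate 0/0
  case — perfectly correlated inhibitory noise exactly at a branching
  point — raises with a diagnostic rather than silently filling a value.

Stability is always judged on the **full** `N × N` Jacobian: the
intra-population eigenvalue `λ_I` that drives branching-point
instabilities is invisible in the two-variable reduction.

## Equilibria and continuation

Equilibria of the noiseless system are found by damped (backtracking)
Newton iteration on the homogeneous two-variable reduction, tolerance
`1e−12` on the drift max-norm, from a 21×21 deterministic grid over
`[V^T − 10, V^T + 10]²` (activation saturation confines all equilibria to
a bounded box around threshold) plus seeded random starts; duplicates are
merged within `1e−6`.  The full `N`-dimensional system uses the same
Newton iteration with the analytic Jacobian and user-supplied starts;
perturbed starts beyond a branching point converge onto the
symmetry-broken equilibria in which the two inhibitory potentials differ.

Branches are continued in a stimulus component by natural-parameter
continuation with warm starts (default step `1e−2`).  A branch is
declared terminated when the warm-started solve fails or jumps by more
than `0.5` in max-norm (it has slid past a fold onto another branch).
Continuation runs from **both endpoints** of a scan so that coexisting
branches on either side of a fold are recovered without pseudo-arclength
machinery.

## Bifurcation detection

Along a continued branch three scalar indicators are tracked:

| kind            | indicator                                   | refinement |
|-----------------|---------------------------------------------|------------|
| saddle-node     | branch termination with real `λ^R → 0`; or sign change of `ℜλ^R_0 · ℜλ^R_1` with a real pair | bisection on existence / on the product |
| Andronov–Hopf   | sign change of `ℜ(λ^R_0 + λ^R_1)` with a conjugate pair | Brent on the trace |
| branching point | sign change of `λ_I`                         | Brent on `λ_I` |

Crossings of `λ_E` are reported as kind `"other"` rather than dropped.
Bisection (not Newton) is used for robustness near folds, where the
branch itself ends; the reported location carries the crossing-eigenvalue
residual (required `< 1e−6`).  Each located point also records whether
the branch is stable on at least one side (`stable_side`): on a typical
fold transect two saddle-node points coexist, one on the stable
(observable) branch and one on a branch that has already lost stability
at a Hopf point, and downstream consumers select the stable-side one.

The analytic *necessary conditions* on the weights — recurrent excitation
strong enough for folds, self-inhibition strong enough for branching
points (which decays like `1/(N−1)`: symmetry breaking is a finite-size
effect), and the quadratic-root condition for Hopf points — are evaluated
exactly, with strict inequalities at the boundary.

## Monte-Carlo simulation

`simulate_paths` integrates the stochastic equations with the
Euler–Maruyama scheme, `V ← V + Δt·drift + √Δt·L ξ` with `L Lᵀ = Σ^B`
(Cholesky when positive definite, eigenvalue factor with null directions
zeroed when singular).  Defaults follow the analytic validation protocol:
`Δt = 1e−3`, horizon `t = 30` (several multiples of the slowest
relaxation time `1/|abscissa|` away from bifurcations), recording at
`t = 30`, 5000 trials, initial condition at the stable equilibrium under
study (statistics are stationary fluctuations around it, so transients
are minimal by construction).  Near bifurcations the weak noise amplitude
`σ^B = 1e−4` keeps the scheme stable.

Each trial owns a generator seeded from `(seed, trial index)`, so any
subset of trials is bit-reproducible independently of ensemble size;
noise is drawn in fixed 500-step blocks per trial, which bounds memory at
`n_trials × 500 × N` doubles without altering any trial's stream.

`empirical_statistics` computes across-trial per-neuron standard
deviations (averaged within populations) and pooled pair correlations
(averaged over all pairs of each type), with standard errors
`SE(std) ≈ std/√(2(n−1))` and `SE(r) ≈ (1−r²)/√(n−3)`.

### What the simulator does and does not emulate

The simulator *is* the synthetic-data generator of the package: it
produces exactly the stationary ensembles the analytic theory describes —
homogeneous populations, constant stimuli, additive white noise with
block-structured correlations.  It deliberately does **not** emulate
heterogeneous weights or sizes within a population, temporally correlated
noise, conductance/spiking dynamics, or time-varying stimuli.  Agreement
between the simulator and the closed form therefore validates the
derivation and its weak-noise assumption; it does not by itself establish
that real cortical circuits satisfy the homogeneity and white-noise
idealizations.

## Parameters of the reference circuit

The package ships a reference parameterization (`default_network`,
`default_noise`): `N_E = 8`, `N_I = 2` (the 4:1 ratio of cortical
circuits), `J_EE = 10`, `J_EI = −70`, `J_IE = 70`, `J_II = −34`,
`τ_E = τ_I = 1` and `ν^max = 1` (these two set the simulation units),
`Λ = 2`, `V^T = 2`, `σ^B = 1e−4`, independent noise.  These weights place
all three bifurcation kinds within moderate stimulus ranges: the fold
condition evaluates to 35/9, the branching condition to 17/9.  On this
circuit the package locates the stable-branch fold at `I_E ≈ 11.860`
(at `I_I = −35`), the Hopf at `I_I ≈ −13.672` and the branching point at
`I_I ≈ 1.164` (at `I_E = 1`).

## Regime classification

`regime_classify` labels an operating point *asynchronous* when all block
correlations are below `c_low = 0.1` **and** each fluctuation scale is
within `s_high = 2` of the decoupled value `σ^B/√(2τ)`; *synchronous*
when any correlation exceeds `c_high = 0.9` **or** the spectral abscissa
is above `−a_slow = −0.05` (critical slowing down); otherwise
*intermediate*.  The thresholds are heuristics for reporting, exposed as
a dataclass, and carry no claim of universality.

## Problem sizes used in the test suite

Property tests use 200 random stable two-population circuits with
population sizes 2–12.  Monte-Carlo validation uses 1000-trial ensembles
(`Δt = 1e−3`, `t = 30`) at five stimuli spanning the asynchronous-to-fold
transect, with an absolute agreement band of 0.05 on pooled correlations
— the Monte-Carlo standard error at 1000 trials.  The weak-convergence
check (halving `Δt`) uses 300 trials at a 10-unit horizon, where the
asynchronous relaxation time is ≈ 1.

## Known limitations

* The closed form covers exactly two populations; for other population
  counts only the Lyapunov route applies (the types accept `P ≥ 2`).
* First-order theory: near Hopf and branching points the predicted
  standard deviations exceed the simulated ones (second-order corrections
  grow there); correlations remain accurate much closer to the
  bifurcations than variances do.
* Fold locations are refined by bisection on branch existence, so the
  residual eigenvalue at the reported location scales like the square
  root of the stimulus resolution; the `1e−6` residual requirement is
  met with ~60 bisection steps.
* Correlations are evaluated only at stable equilibria approaching a
  bifurcation from the stable side; the package never reports covariance
  *at* a marginal point.
* Two-parameter bifurcation diagrams, codimension-two points and global
  bifurcations (homoclinic, torus, limit point of cycles) are out of
  scope; periodic orbits are not continued.
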