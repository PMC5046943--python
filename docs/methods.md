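# Methods

## The model and the coupling

`hybridrd` simulates one-dimensional reaction–diffusion systems with a
*spatially hybrid* description.  The domain Ω = [x_lo, x_hi] is split
into a stochastic region Ω_c = [x_lo, I1], described by a
compartment-based model (the reaction–diffusion master equation, RDME:
well-mixed boxes of width h, per-particle hop rate d = D/h² to each
neighbour, reactions within boxes), and a deterministic region
Ω_p = [I0, x_hi], described by the mean-field PDE

    ∂u/∂t = D ∂²u/∂x² + R(u),

discretised on a mesh of spacing Δx_p.  The regions share an overlap
[I0, I1] of m = (I1 − I0)/h compartments in which both descriptions are
maintained simultaneously.  The coupling conditions are:

* **Flux matching at I1** (Neumann-like, acting on the compartments).
  Per step of length Δt the expected net transfer into the compartment
  adjacent to I1 is

      ψ = (D Δt / h²) (Û_ghost − Û_adj),

  where Û_c = h·u(c) are the expected counts of width-h compartments
  centred at I1 + h/2 (a "ghost" compartment living on the PDE mesh)
  and I1 − h/2, with u linearly interpolated between mesh nodes.  A
  single uniform draw r1 < |ψ| adds (ψ > 0) or removes (ψ < 0) one
  particle.  On affine profiles ψ collapses exactly to Fick's law,
  D·(∂u/∂x)·Δt, which the test-suite asserts to 1e-14.  Removal from an
  already-empty compartment is skipped and counted; the skip rate is a
  published diagnostic (a high rate flags that Δt or the interface
  placement is wrong for the problem).
* **Concentration matching at I0** (Dirichlet, acting on the PDE).
  Before each PDE step the node on I0 is set to the mean density of the
  two compartments straddling I0, (A_left + A_right)/(2h).  A one-sided
  variant (left compartment only) is available behind
  `dirichlet_one_sided` for sensitivity checks.

One coupled step executes, in order: interface transfer at I1 → at most
one stochastic event in Ω_c (see below) → clock advance → Dirichlet
refresh at I0 and one θ-scheme PDE step.  All coupling formulas operate
on densities/counts rather than single-particle probabilities; the two
formulations differ only by the constant factor N, which cancels.

## Stochastic stepping

The compartment model is *time driven*: each fixed step carries at most
one event.  With total propensity α0 (jumps plus reactions), an event
occurs with probability α0·Δt and is selected proportionally to its
propensity by one uniform draw against the cumulative table.  This
interpretation requires α0·Δt ≪ 1; the runners warn above 0.1 and raise
at ≥ 1 (as does |ψ| ≥ 1 for the interface channel).  The shipped study
configurations choose Δt so that the worst-case α0·Δt stays near 0.1,
which is why they use much smaller steps (1e-5 .. 4e-5) than a
PDE-stability argument alone would suggest; Δt shrinks like h² when
the grid is refined.

The fully stochastic reference simulator advances the same per-step
Bernoulli process by sampling the number of empty steps between events
from the corresponding geometric distribution (the state is frozen
between events, so this is distributionally exact, not an
approximation).  The hybrid runner cannot skip steps — the PDE advances
every Δt — so its inner loop is a compiled kernel; the kernel and the
plain-numpy per-step operations implement identical rules and are
cross-checked in the tests (deterministically where possible,
statistically otherwise).

Reaction channels use standard RDME conventions: decay μ·A_k;
zeroth-order production J into the source compartment; logistic
(Fisher) kinetics as birth A → 2A at rate k1·A_k plus pair
annihilation A + A → A at rate (k2/h)·A_k(A_k − 1), whose mean field
recovers k1·u − k2·u².

## PDE solver

A θ-scheme (default θ = 1/2, Crank–Nicolson) with the reaction term
treated explicitly (IMEX): unconditionally stable diffusion, no
nonlinear solve, and the explicit reaction error is negligible at the
Δt the stochastic side imposes anyway.  Zero-flux and influx
(−D ∂u/∂x = J) boundaries use second-order ghost-node reflection; with
trapezoidal mass accounting the zero-flux scheme conserves mass to
round-off.  The tridiagonal system is pre-factorised once per operator
(Thomas factors for the compiled kernel, banded LAPACK solves for the
Python path).  Observed convergence order on a decaying cosine
eigenmode is 2.0.

Explicit stepping (θ < 1/2) enforces the stability bound
D·Δt/Δx_p² ≤ 1/(2(1−2θ)) and exists only for cross-checking.

## Reference solutions

* **Pure diffusion, step initial data** on [−1, 1] with zero-flux ends:
  method of images.  The even periodic extension of 1_{[0,1]} has
  period 4 and support ∪_k [0, 2] + 4k, giving
  u(x,t) = (N/2) Σ_k [erf((x−4k)/s) − erf((x−4k−2)/s)], s = 2√(Dt),
  truncated when an added image pair contributes < 1e-12 (at least
  three pairs).  The series is validated against an independent cosine
  spectral sum to 1e-9 and against the Crank–Nicolson solver.  Note the
  slowest zero-flux mode decays at rate D·π²/4 (domain half-length 2),
  so the profile is flat to 1e-8 only for t ≳ 400 at D = 0.025.
* **Morphogen steady state** (production J at x = 1, decay μ,
  zero flux at x = −1): u_s(x) = J·cosh(λ(x+1))/(√(Dμ)·sinh 2λ),
  λ = √(μ/D), with ∫u_s = J/μ exactly.  The transient *mass* obeys
  dM/dt = J − μM exactly, so M(t) = (J/μ)(1 − e^{−μt}); at t = 20 with
  μ = 0.2 this is 613.6, i.e. the system is ~98% of the way to the
  steady level 625 — comparisons at t = 20 must use the transient
  value, since the remaining deterministic deficit (≈11 particles)
  exceeds the ensemble noise of a 100-repeat mean.
* **Fisher–KPP front speed**: the deterministic minimum speed is
  2√(D k1); the discrete stochastic model travels strictly slower.
  Speeds are estimated from the total mass as
  v = (k2/k1)·ΔM/Δt (the front height approaches k1/k2), smoothed with
  a trailing 5-time-unit moving average.

## Metrics

Output is binned on the width-h grid tiling Ω: compartment bins report
A/h, PDE bins the trapezoidal bin average, overlap bins the compartment
value by default (the equal-weight mean of both descriptions for
adaptive runs, where interfaces differ between repeats).  Total mass
counts each point once: compartments own [x_lo, I1], the PDE integral
runs over (I1, x_hi].  The normalised error of an ensemble mean against
a reference profile is

    E = (h/N) Σ_bins |mean − reference|,

the total absolute expected-count discrepancy per particle.  Ensemble
variance uses the unbiased per-bin sample variance; variance
comparisons use 95% percentile-bootstrap intervals (1000 resamples) —
the bootstrap is a package choice, any distribution-free interval
would do.

Two validation subtleties are handled explicitly.  First, the
Monte-Carlo floor of E is not constant in time: with unbiased per-bin
means, E has expectation (h/N)·√(2/π)·Σ_b SE_b(t), which changes as
mass moves between the (noisy) stochastic and (quiet) PDE regions.
Drift tests therefore examine E minus this floor — the bias
component — rather than raw E.  Second, front-speed comparisons use
only post-transient data: raw per-unit-time estimates restricted to
t ∈ [10, 20], their interval means, and trailing-window moving
averages evaluated where the window lies inside the interval (a
trailing window anchored at t = 10 would otherwise average over the
start-up transient of the steep initial step).

## Adaptive interface

Every η steps the interfaces may move one compartment width, both
together (the overlap width m is preserved).  Probes: the two
compartments straddling I0 and the PDE density at I1 ± h/2 converted
to counts per compartment.  All four above u_max → the PDE region
expands one h toward the stochastic side; all four below u_max − δu →
the compartment region expands back; anything else holds (hysteresis
against interface flapping).  Remapping is conservative: newly meshed
PDE nodes take the covering compartment's density; the nodes over a
vacated compartment are set to the constant whose trapezoidal integral
equals its count exactly; a newly created compartment takes the rounded
integral of the PDE density over its extent; vacated nodes are then
discarded.  Each move therefore changes total mass by at most one
particle (round-off of one compartment), which the runner records as a
diagnostic along with the move history.

For the travelling wave, u_max = 10.5 and δu = 1.0 (against a plateau
of k1/k2·h = 20 particles per compartment) keep the entire front inside
the stochastic region while the PDE absorbs the plateau behind it.

## Study configurations and problem sizes

The canonical configurations in `hybridrd.configs` are the package's
study conditions:

| problem | domain | h | Δx_p | overlap | Δt | repeats | T |
|---|---|---|---|---|---|---|---|
| diffusion (uniform/step) | [−1,1], D=0.025, N=1000 | 0.05 | 0.01 | [0, 0.1] | 8e-6 (5e-6 step_left) | 100 | 10 |
| morphogen | [−1,1], D=0.05, μ=0.2, J=125 | 0.05 | 0.01 | [0, 0.1] | 2e-5 (3.1e-6 fully stoch.) | 100 | 20 |
| Fisher wave | [−50,50], D=1, k1=1, k2=0.1 | 2 | 0.5 | [0, 2] | 4e-5 | 200 | 20 |

The travelling-wave ensembles use 200 repeats; the mean profiles and
smoothed speed estimates are stable at that size, and the comparison
against the fully stochastic model is made at identical size.  The
parameter-sensitivity scans (h ∈ {0.025, 0.05, 0.1, 0.2},
Δx_p ∈ {0.005, 0.01, 0.02}, m ∈ {1, 2, 4}; step initial condition,
error at t = 1) default to 100 repeats: an a-priori noise analysis
shows the Monte-Carlo floor of E scales like 1/√h and would mask the
spatial-discretisation trend at small ensemble sizes.  For the h-scan
the PDE spacing is snapped to the nearest exact divisor of h.

## What the generator emulates — and what it does not

All inputs are programmatically generated initial conditions (uniform,
step, logistic-front step) plus configuration; there is no external
data.  The step initial conditions are deliberately extreme stress
tests (all mass on one side of the interface, in either direction) and
the uniform case probes equilibrium maintenance; real applications
would place the PDE region over the *high*-density part of the domain.
Passing tests demonstrate that the coupling transfers mass and
fluctuations correctly for linear diffusion, a linear
production–decay balance and one nonlinear front-propagation problem
in 1-D with a single species and a fixed diffusion coefficient.  They
say nothing about multi-species systems, 2-D/3-D domains,
concentration-dependent diffusion, or off-lattice (Brownian) regimes —
all outside this package's scope.

## Numerical choices and degenerate inputs

* Grid alignment is validated eagerly: (I1−I0)/h, (I0−x_lo)/h, h/Δx_p
  and the mesh span must be integers (to 1e-9 relative); the ghost
  centre I1 + h/2 must lie inside the PDE mesh.
* Initial counts are apportioned by largest-remainder rounding, so the
  total is exact whenever the quotas allow; any residual is ≤ 1 per
  compartment.
* The PDE field is clipped at zero after each step (θ-schemes can
  undershoot near steep fronts by round-off-scale amounts).
* Empty systems (N = 0, no production) are valid and remain identically
  zero.
* Per-bin 3-SE agreement checks in the tests require ≥ 97.5% of bins in
  band: with ~40 bins, an occasional chance excursion beyond 3σ is
  expected even under exact agreement.
* One RNG stream per repeat (`seed + repeat_index`); runs are
  reproducible bit-for-bit given the seed.

## Known limitations

* The time-driven scheme spends one Bernoulli trial per step; at high
  propensity it forces very small Δt.  An event-driven variant would
  lift this but is out of scope.
* The interface transfer executes at most one particle per step; ψ ≥ 1
  is treated as a configuration error rather than silently executing
  multiple transfers.
* Mass is conserved exactly per realisation only in the fully
  stochastic model; the coupled scheme conserves it in expectation
  (verified to within 3 SE over ensembles, with no detectable drift).
* The Dirichlet average at I0 is first-order in h; overall interface
  error grows with h (visible in the h-sensitivity scan).
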