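# hybridrd

Hybrid deterministic/stochastic simulation of one-dimensional
reaction–diffusion systems, coupling a mean-field PDE description to a
compartment-based stochastic (RDME) description through an overlap
region.

## Why

Compartment-based stochastic simulation resolves the fluctuations that
dominate reaction–diffusion dynamics at low copy number — morphogen
gradients near their decay edge, the leading edge of an invasion front —
but its cost grows with the number of particles.  The mean-field PDE

    ∂u/∂t = D ∂²u/∂x² + R(u)

is cheap and accurate exactly where the stochastic model is expensive:
at high copy number.  `hybridrd` runs both at once, each where it is
valid: a stochastic region Ω_c = [x_lo, I1] of well-mixed compartments
(width h, hop rate D/h²), a PDE region Ω_p = [I0, x_hi] on a fine mesh,
and an overlap [I0, I1] where both live.  Two conditions couple them:

* at **I1**, particles cross into/out of the stochastic region with
  per-step probability ψ = (DΔt/h²)(Û_ghost − Û_adj), the discrete
  Fickian flux computed from the PDE profile;
* at **I0**, the PDE node is pinned to the mean density of the two
  compartments straddling the interface (a Dirichlet condition).

Flux matching at one end and concentration matching at the other keep
both the mean *and* the fluctuations consistent across the interface.
An optional adaptive mode moves the interface pair in increments of h,
following regions of low copy number (e.g. a travelling front) with a
hysteresis criterion (u_max, δu, checked every η steps).

Audience: anyone building or validating multiscale stochastic
reaction–diffusion simulations — the package provides the coupled
simulator, a fully stochastic reference simulator, the deterministic
PDE solver, closed-form references (image-series diffusion solution,
morphogen steady state), and the validation metrics (normalised error,
wave-speed estimator, ensemble variance).

## Worked example

A morphogen gradient: molecules produced at rate J = 125 at x = 1,
decaying at μ = 0.2 everywhere, diffusing with D = 0.05, starting from
an empty domain.  The compartment model covers [−1, 0.1], the PDE
[0, 1]:

```python
import hybridrd as hr

cfg = hr.morphogen_config(seed=1)      # 100 repeats to t = 20
traj = hr.run_hybrid(cfg)

M = traj.mass[:, -1]
print("mean total mass at t=20:", round(M.mean(), 1),
      "+/-", round(M.std(ddof=1) / len(M) ** 0.5, 1))
print("steady-state prediction J/mu:", cfg.J / cfg.mu)

ref = hr.morphogen_steady_state(traj.x_centres, cfg.D, cfg.mu, cfg.J)
E = hr.normalized_error(traj.density[:, -1].mean(axis=0), ref,
                        cfg.J / cfg.mu, cfg.h)
print("normalised profile error vs closed form:", round(E, 4))
```

prints

```
mean total mass at t=20: 613.2 +/- 1.0
steady-state prediction J/mu: 625.0
normalised profile error vs closed form: 0.0187
```

The mean mass sits on the exact mean-field transient
(J/μ)(1 − e^{−μt}) = 613.6 — at t = 20 the system is ~98% of the way
to the steady level 625 — and the ensemble-mean profile matches the
closed-form gradient u_s(x) = J·cosh(λ(x+1))/(√(Dμ)·sinh 2λ) to well
under 2% of a particle per bin.

The same API drives the other study problems:
`hr.diffusion_config(...)` (equilibrium and step-relaxation tests
against the image-series analytic solution) and
`hr.fisher_wave_config(adaptive=...)` (a stochastic Fisher–KPP front,
whose speed the mass record M(t) yields via v = (k2/k1)·dM/dt).

There is also a CLI:

```bash
hybridrd simulate --config config_template.yaml --mode hybrid --out run.csv
hybridrd wavespeed --repeats 50 --seed 3 --out speeds.csv
hybridrd sensitivity --scan h --values 0.025,0.05,0.1,0.2 --out scan.csv
```

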