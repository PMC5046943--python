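"""Canonical study configurations for the three test problems.

These fix the *study conditions* used throughout the test-suite and the
reproduction script: domain geometry, physical rates, particle numbers
and ensemble sizes for (i) pure diffusion on [-1, 1] with uniform and
step initial data, (ii) morphogen-gradient formation (boundary
production, uniform decay), and (iii) a stochastic Fisher-KPP
travelling wave on [-50, 50].

Time steps are chosen per problem so that the worst-case total event
propensity satisfies ``alpha0 * dt <= ~0.1`` (the single-event-per-step
regime the coupled algorithm requires); they shrink like h² when the
compartment grid is refined.
"""

from __future__ import annotations

from .core import SimulationConfig

__all__ = [
    "diffusion_config",
    "morphogen_config",
    "fisher_wave_config",
    "sensitivity_config",
]


def diffusion_config(ic_name: str = "uniform", **overrides) -> SimulationConfig:
    """Pure diffusion on [-1, 1]: D = 0.025, h = 0.05, dxp = 0.01,
    overlap [0, 0.1], N = 1000 particles, 100 repeats to t = 10.

    ``step_left`` starts with every particle in the stochastic region,
    the worst case for the event rate, hence its smaller default dt.
    """
    dt = 5e-6 if ic_name == "step_left" else 8e-6
    base = dict(
        domain_lo=-1.0,
        domain_hi=1.0,
        D=0.025,
        dt=dt,
        h=0.05,
        dxp=0.01,
        I0=0.0,
        I1=0.1,
        T_final=10.0,
        N=1000,
        reaction="none",
        repeats=100,
        ic_name=ic_name,
        snapshot_interval=0.1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def morphogen_config(stochastic: bool = False, **overrides) -> SimulationConfig:
    """Morphogen gradient on [-1, 1]: production J = 125 at x = 1, decay
    mu = 0.2, D = 0.05; empty start, 100 repeats to t = 20.

    The steady state holds J/mu = 625 particles, ~100 of them in the
    compartment region; the fully stochastic variant carries all 625 as
    discrete particles and needs a correspondingly smaller dt.
    """
    base = dict(
        domain_lo=-1.0,
        domain_hi=1.0,
        D=0.05,
        dt=3.125e-6 if stochastic else 2e-5,
        h=0.05,
        dxp=0.01,
        I0=0.0,
        I1=0.1,
        T_final=20.0,
        N=0,
        reaction="morphogen",
        mu=0.2,
        J=125.0,
        repeats=100,
        ic_name="uniform",
        snapshot_interval=0.1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def fisher_wave_config(adaptive: bool = False, **overrides) -> SimulationConfig:
    """Stochastic Fisher-KPP front on [-50, 50]: D = 1, k1 = 1, k2 = 0.1,
    h = 2, dxp = 0.5, overlap [0, 2]; plateau k1/k2 = 10 initially fills
    x >= 0, the front advances leftward at roughly (but strictly below)
    the deterministic minimum speed 2*sqrt(D*k1) = 2.

    Adaptive runs use the interface-detection thresholds
    u_max = 10.5, delta_u = 1.0 checked every eta = 50 steps, and report
    overlap bins as the mean of the two descriptions.
    """
    base = dict(
        domain_lo=-50.0,
        domain_hi=50.0,
        D=1.0,
        dt=4e-5,
        h=2.0,
        dxp=0.5,
        I0=0.0,
        I1=2.0,
        T_final=20.0,
        N=500,  # nominal k1/k2 * 50 plateau mass, used only for normalisation
        reaction="fisher",
        k1=1.0,
        k2=0.1,
        repeats=200,
        ic_name="fisher_step",
        snapshot_interval=1.0,
        adaptive=adaptive,
    )
    if adaptive:
        base.update(u_max=10.5, delta_u=1.0, eta=50, overlap_output="average")
    base.update(overrides)
    return SimulationConfig(**base)


def sensitivity_config(
    h: float = 0.05,
    dxp: float = 0.01,
    m: int | None = None,
    repeats: int = 100,
    **overrides,
) -> SimulationConfig:
    """Diffusion with the step initial condition (mass in [0, 1]) run to
    t = 1, for error scans over h, dxp and the overlap width m.

    The overlap is m compartments wide (default: as close to 0.1 as the
    compartment grid allows, at least one compartment); dt scales with
    h² to stay in the single-event regime at any compartment width.
    """
    if m is None:
        m = max(1, round(0.1 / h))
    if round(h / dxp) < 1 or abs(h / dxp - round(h / dxp)) > 1e-9:
        # the PDE mesh must subdivide the compartment grid exactly
        dxp = h / max(1, round(h / dxp))
    T_final = float(overrides.pop("T_final", 1.0))
    # target dt ~ 0.008 h^2 keeps alpha0*dt <= ~0.1 at any compartment
    # width; snapped so an integer number of steps spans the run
    dt = T_final / max(1, round(T_final / (0.008 * h * h)))
    base = dict(
        domain_lo=-1.0,
        domain_hi=1.0,
        D=0.025,
        dt=dt,
        h=h,
        dxp=dxp,
        I0=0.0,
        I1=m * h,
        T_final=T_final,
        N=1000,
        reaction="none",
        repeats=repeats,
        ic_name="step_right",
        snapshot_interval=T_final,
    )
    base.update(overrides)
    return SimulationConfig(**base)
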