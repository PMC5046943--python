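"""The coupled step: flux matching at I1, Dirichlet matching at I0.

Per time step the coupled algorithm executes, in order:

1. *Interface transfer at I1.*  The expected net number of particles
   crossing into the interface-adjacent compartment during ``dt`` is
   estimated from the PDE profile,

       psi = (D dt / h²) (Û_ghost − Û_adj),

   where Û_c = h·u(c) are expected counts of width-h (ghost)
   compartments centred at I1 + h/2 and I1 − h/2, with u linearly
   interpolated from the PDE mesh.  A uniform draw r1 < |psi| adds
   (psi > 0) or removes (psi < 0) one particle.  On affine profiles psi
   reduces exactly to Fick's law, D·slope·dt.
2. *One stochastic event* in the compartment region (see
   :mod:`hybridrd.ssa`).
3. *Dirichlet matching at I0*: the PDE node on I0 is set to the mean
   density of the two compartments straddling I0, then the PDE is
   advanced one θ-scheme step.

Working in density units absorbs the single-particle probability
scaling (p = u/N): all formulas are linear in N, so the per-particle
description and the count description coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (
    DomainPartition,
    HybridState,
    ReactionSpec,
    SimulationConfig,
    Trajectory,
    build_partition,
    make_initial_condition,
    output_bins,
)
from .pde import PDEProblem, ThetaOperator
from .analysis import binned_density, total_mass
from .ssa import ssa_time_step, _kernel_reaction_params, _snapshot_plan

__all__ = [
    "InterfaceFlux",
    "interpolate_pde_at_centre",
    "interface_transfer_probability",
    "apply_interface_transfer",
    "apply_dirichlet_coupling",
    "hybrid_step",
    "run_hybrid",
    "pde_problem_for",
]


@dataclass(frozen=True)
class InterfaceFlux:
    """Expected net particle transfer into the compartment adjacent to I1
    during one step (signed; positive = into the compartment region),
    with the interpolated expected counts it was derived from."""

    psi: float
    expected_count_adjacent: float
    expected_count_ghost: float


def interpolate_pde_at_centre(
    u: np.ndarray, partition: DomainPartition, x_c: float
) -> float:
    """Linear interpolation of the PDE density at ``x_c`` (exact at nodes)."""
    i, f = _interp_weights(partition, x_c, len(u))
    return float(u[i] * (1.0 - f) + u[i + 1] * f)


def _interp_weights(
    partition: DomainPartition, x_c: float, n_nodes: int
) -> tuple[int, float]:
    pos = (x_c - partition.I0) / partition.dxp
    if pos < -1e-9 or pos > n_nodes - 1 + 1e-9:
        raise ValueError(
            f"position {x_c} lies outside the PDE region "
            f"[{partition.I0}, {partition.domain_hi}]"
        )
    i = int(np.floor(pos + 1e-12))
    i = min(max(i, 0), n_nodes - 2)
    return i, pos - i


def interface_transfer_probability(
    u: np.ndarray,
    partition: DomainPartition,
    D: float,
    dt: float,
    h: float,
) -> InterfaceFlux:
    """The Bernoulli transfer probability for this step (see module docs)."""
    c_adj = partition.I1 - h / 2.0
    c_gh = partition.I1 + h / 2.0
    U_adj = h * interpolate_pde_at_centre(u, partition, c_adj)
    U_gh = h * interpolate_pde_at_centre(u, partition, c_gh)
    psi = (D * dt / h**2) * (U_gh - U_adj)
    if abs(psi) >= 1.0:
        raise RuntimeError(
            f"|psi| = {abs(psi):.3g} >= 1: more than one interface transfer "
            "would be needed per step; reduce dt"
        )
    return InterfaceFlux(float(psi), float(U_adj), float(U_gh))


def apply_interface_transfer(
    A: np.ndarray,
    flux: InterfaceFlux,
    rng: np.random.Generator,
    diagnostics: dict | None = None,
) -> np.ndarray:
    """Bernoulli-execute the transfer on the last compartment.

    Removal from an empty compartment is skipped (and counted in
    ``diagnostics['skipped_removals']`` when a dict is supplied): counts
    never go negative, and a high skip rate flags a regime violation.
    """
    A = np.asarray(A).copy()
    if rng.random() < abs(flux.psi):
        if flux.psi > 0:
            A[-1] += 1
        elif A[-1] > 0:
            A[-1] -= 1
        elif diagnostics is not None:
            diagnostics["skipped_removals"] = diagnostics.get("skipped_removals", 0) + 1
    return A


def apply_dirichlet_coupling(
    u: np.ndarray,
    A: np.ndarray,
    partition: DomainPartition,
    one_sided: bool = False,
) -> np.ndarray:
    """Set the PDE node on I0 to the mean density of the two compartments
    straddling I0 (or the left one only, for sensitivity checks)."""
    u = np.asarray(u, dtype=float).copy()
    n = partition.overlap_index_start
    h = partition.h
    if one_sided:
        u[0] = A[n - 1] / h
    else:
        u[0] = (A[n - 1] + A[n]) / (2.0 * h)
    return u


def pde_problem_for(config: SimulationConfig) -> PDEProblem:
    """The PDE-side physics implied by a simulation config."""
    reaction, mu, k1, k2 = "none", 0.0, 0.0, 0.0
    right_bc, J = "zero_flux", 0.0
    if config.reaction == "decay":
        reaction, mu = "decay", config.mu
    elif config.reaction == "morphogen":
        reaction, mu = "decay", config.mu
        right_bc, J = "influx", config.J
    elif config.reaction == "fisher":
        reaction, k1, k2 = "logistic", config.k1, config.k2
    return PDEProblem(
        D=config.D,
        reaction=reaction,
        mu=mu,
        k1=k1,
        k2=k2,
        right_bc=right_bc,
        J=J,
        left_bc="dirichlet",
        theta=config.theta,
    )


def hybrid_step(
    state: HybridState,
    config: SimulationConfig,
    partition: DomainPartition,
    rng: np.random.Generator,
    operator: ThetaOperator | None = None,
    spec: ReactionSpec | None = None,
    diagnostics: dict | None = None,
) -> HybridState:
    """One step of the coupled algorithm (reference numpy path).

    The ensemble runner :func:`run_hybrid` uses a compiled kernel with
    identical per-step rules; this function is the readable/testable
    form and is interchangeable statistically.
    """
    if operator is None:
        operator = ThetaOperator(
            pde_problem_for(config), len(state.u), config.dxp, config.dt
        )
    if spec is None:
        spec = ReactionSpec.for_config(config)
    flux = interface_transfer_probability(
        state.u, partition, config.D, config.dt, config.h
    )
    A = apply_interface_transfer(state.A, flux, rng, diagnostics)
    A = ssa_time_step(A, config.dt, config.D, config.h, spec, rng)
    t = state.t + config.dt
    u = apply_dirichlet_coupling(state.u, A, partition, config.dirichlet_one_sided)
    u = operator.step(u, dirichlet_value=u[0])
    np.clip(u, 0.0, None, out=u)
    return HybridState(A=A, u=u, t=t)


# ---------------------------------------------------------------------------
# ensemble runner (compiled inner loop)


def _kernel_args(config: SimulationConfig, partition: DomainPartition,
                 operator: ThetaOperator) -> dict:
    n_nodes = len(partition.pde_nodes)
    i_mm, f_mm = _interp_weights(partition, partition.I1 - config.h / 2, n_nodes)
    i_gh, f_gh = _interp_weights(partition, partition.I1 + config.h / 2, n_nodes)
    mu, k1, k2oh, _, _ = _kernel_reaction_params(
        config, partition.n_compartments, stochastic=False
    )
    p = operator.problem
    pde_rx = {"none": 0, "decay": 1, "logistic": 2}[p.reaction]
    return dict(
        d=config.D / config.h**2,
        dt=config.dt,
        h=config.h,
        D=config.D,
        i_mm=i_mm,
        f_mm=f_mm,
        i_gh=i_gh,
        f_gh=f_gh,
        n_left=partition.overlap_index_start - 1,
        one_sided=config.dirichlet_one_sided,
        mu=mu,
        k1=k1,
        k2oh=k2oh,
        wf=operator._wf,
        inv_bp=1.0 / operator._bp,
        cp=operator._cp,
        r_mesh=operator.r,
        theta=p.theta,
        influx_rhs=operator._influx_rhs,
        pde_rx=pde_rx,
        pde_mu=p.mu,
        pde_k1=p.k1,
        pde_k2=p.k2,
        rhs=np.empty(n_nodes),
    )


def _check_diag(diag: np.ndarray, rep: int) -> None:
    if diag[4] == _kernels.ERR_PSI:
        raise RuntimeError(
            f"|psi| reached {diag[5]:.3g} >= 1 in repeat {rep}; reduce dt"
        )
    if diag[4] == _kernels.ERR_ALPHA:
        raise RuntimeError(
            f"alpha0*dt reached {diag[0]:.3g} >= 1 in repeat {rep}; reduce dt"
        )


def run_hybrid(config: SimulationConfig) -> Trajectory:
    """Ensemble of coupled simulations; one RNG stream per repeat
    (``seed + repeat``), snapshots every ``snapshot_interval``.

    Adaptive-interface configs are dispatched to
    :func:`hybridrd.adaptive.run_adaptive`.
    """
    if config.adaptive:
        from .adaptive import run_adaptive

        return run_adaptive(config)
    partition = build_partition(config)
    operator = ThetaOperator(
        pde_problem_for(config), len(partition.pde_nodes), config.dxp, config.dt
    )
    kargs = _kernel_args(config, partition, operator)
    spsnap, nsnap, times = _snapshot_plan(config)
    state0 = make_initial_condition(config, partition)
    B = len(output_bins(config))
    C = partition.n_compartments
    n = partition.overlap_index_start

    density = np.empty((config.repeats, nsnap + 1, B))
    mass = np.empty((config.repeats, nsnap + 1))
    diag_total = np.zeros(6)
    for rep in range(config.repeats):
        state = state0.copy()
        diag = np.zeros(6)
        _kernels.seed_rng(config.seed + rep)
        density[rep, 0] = binned_density(state, partition, config.overlap_output)
        mass[rep, 0] = total_mass(state, partition)
        for s in range(1, nsnap + 1):
            _kernels.hybrid_chunk(state.A, state.u, spsnap, diag=diag, **kargs)
            _check_diag(diag, rep)
            state.t = times[s]
            density[rep, s] = binned_density(state, partition, config.overlap_output)
            mass[rep, s] = total_mass(state, partition)
        diag_total[0] = max(diag_total[0], diag[0])
        diag_total[1] += diag[1]
        diag_total[2] += diag[2]
        diag_total[3] += diag[3]
        diag_total[5] = max(diag_total[5], diag[5])
    if diag_total[0] > 0.1:
        warnings.warn(
            f"alpha0*dt reached {diag_total[0]:.3g} > 0.1 during the run",
            stacklevel=2,
        )
    regime = np.array(
        ["compartment"] * n + ["overlap"] * (C - n) + ["pde"] * (B - C)
    )
    return Trajectory(
        times=times,
        x_centres=output_bins(config),
        density=density,
        mass=mass,
        regime=regime,
        config=config,
        mode="hybrid",
        diagnostics={
            "max_alpha0_dt": float(diag_total[0]),
            "skipped_removals": float(diag_total[1]),
            "events": float(diag_total[2]),
            "interface_transfers": float(diag_total[3]),
            "max_abs_psi": float(diag_total[5]),
        },
    )
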