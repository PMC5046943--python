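"""Adaptive placement of the model interface.

For problems whose low-copy-number region moves (e.g. a travelling
front), the interface pair (I0, I1) is moved in increments of one
compartment width ``h`` based on a local density criterion checked
every ``eta`` steps: when the densities near both interfaces (in
particles per compartment) all exceed ``u_max`` the PDE region expands
one compartment toward the stochastic region; when they all fall below
``u_max - delta_u`` (hysteresis) the compartment region expands back.
Both interfaces move together, preserving the overlap width ``m``.

State is remapped conservatively across a move: newly meshed PDE nodes
take the density of the compartment that covered them, the PDE nodes
over a vacated compartment are reset to that compartment's density, and
a newly created compartment integrates the PDE density over its extent
(rounded to an integer).  Every move changes the total mass by at most
one particle; vacated PDE nodes are discarded after the hand-over.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .core import (
    DomainPartition,
    HybridState,
    SimulationConfig,
    Trajectory,
    build_partition,
    make_initial_condition,
    output_bins,
)
from .pde import ThetaOperator
from .analysis import binned_density, pde_bin_average, total_mass
from .ssa import _snapshot_plan

__all__ = ["check_move", "move_interface", "overlap_average", "run_adaptive"]

logger = logging.getLogger(__name__)

EXPAND_PDE = "expand_pde"
EXPAND_COMPARTMENTS = "expand_compartments"
NONE = "none"


def check_move(
    state: HybridState, config: SimulationConfig, partition: DomainPartition
) -> str:
    """Direction in which to move the interfaces, if any.

    Probes the two compartments straddling I0 and the PDE density at
    I1 ± h/2 (converted to counts per compartment).  All four must agree
    before a move is triggered; the band [u_max - delta_u, u_max] moves
    nothing (hysteresis against interface flapping).
    """
    from .coupling import interpolate_pde_at_centre

    n = partition.overlap_index_start
    h = partition.h
    probes = np.array(
        [
            float(state.A[n - 1]),
            float(state.A[n]),
            h * interpolate_pde_at_centre(state.u, partition, partition.I1 - h / 2),
            h * interpolate_pde_at_centre(state.u, partition, partition.I1 + h / 2),
        ]
    )
    if np.all(probes > config.u_max):
        return EXPAND_PDE
    if np.all(probes < config.u_max - config.delta_u):
        return EXPAND_COMPARTMENTS
    return NONE


def move_interface(
    state: HybridState, partition: DomainPartition, direction: str
) -> tuple[HybridState, DomainPartition]:
    """Shift both interfaces by one compartment width in ``direction``.

    Returns the remapped (state, partition); a move that would leave
    fewer than one compartment on either side of I0, or push the ghost
    compartment outside the PDE mesh, is refused and the original
    objects are returned unchanged (identity-comparable).
    """
    if direction == NONE:
        return state, partition
    h, dxp, w = partition.h, partition.dxp, partition.w
    n = partition.overlap_index_start
    m = partition.m
    l = partition.l
    if direction == EXPAND_PDE:
        if n - 1 < 1:
            logger.info("interface move refused: would leave n = %d < 1", n - 1)
            return state, partition
        fill = np.full(w, state.A[n - 1] / h)  # newly meshed [I0-h, I0)
        u_new = np.concatenate([fill, state.u])
        # hand the vacated compartment (adjacent to I1) to the PDE: set the
        # nodes over its extent to the constant whose trapezoidal integral
        # over the bin equals the compartment count exactly (the node on
        # I1, shared with the continuing PDE region, keeps its value)
        c_exact = (state.A[-1] - u_new[l + w] * dxp / 2.0) / (h - dxp / 2.0)
        u_new[l : l + w] = max(c_exact, 0.0)
        A_new = state.A[:-1].copy()
        part_new = DomainPartition(
            compartment_edges=partition.compartment_edges[:-1],
            compartment_centres=partition.compartment_centres[:-1],
            pde_nodes=np.concatenate(
                [partition.pde_nodes[0] - dxp * np.arange(w, 0, -1),
                 partition.pde_nodes]
            ),
            overlap_index_start=n - 1,
            w=w,
            l=l,
            h=h,
            dxp=dxp,
        )
        return HybridState(A_new, u_new, state.t), part_new
    if direction == EXPAND_COMPARTMENTS:
        new_I1 = partition.I1 + h
        if new_I1 + h / 2.0 > partition.domain_hi + 1e-9:
            logger.info(
                "interface move refused: ghost compartment centre %.6g would "
                "leave the PDE region", new_I1 + h / 2.0
            )
            return state, partition
        weights = np.ones(w + 1)
        weights[0] = weights[-1] = 0.5
        mass_bin = float(np.dot(state.u[l : l + w + 1], weights) * dxp)
        A_new = np.concatenate([state.A, [int(round(mass_bin))]]).astype(np.int64)
        u_new = state.u[w:].copy()  # vacated nodes discarded after hand-over
        edges_new = np.concatenate(
            [partition.compartment_edges, [new_I1]]
        )
        part_new = DomainPartition(
            compartment_edges=edges_new,
            compartment_centres=0.5 * (edges_new[:-1] + edges_new[1:]),
            pde_nodes=partition.pde_nodes[w:],
            overlap_index_start=n + 1,
            w=w,
            l=l,
            h=h,
            dxp=dxp,
        )
        return HybridState(A_new, u_new, state.t), part_new
    raise ValueError(f"unknown direction {direction!r}")


def overlap_average(
    u: np.ndarray, A: np.ndarray, partition: DomainPartition
) -> np.ndarray:
    """Per overlap bin, the equal-weight mean of the two descriptions:
    (bin-averaged PDE density + A/h) / 2."""
    n = partition.overlap_index_start
    m = partition.m
    pde_bins = pde_bin_average(u, partition)[:m]
    return 0.5 * (pde_bins + np.asarray(A[n:]) / partition.h)


def run_adaptive(config: SimulationConfig) -> Trajectory:
    """Ensemble runner with the adaptive interface (cf.
    :func:`hybridrd.coupling.run_hybrid`, which dispatches here)."""
    from .coupling import _check_diag, _kernel_args, pde_problem_for

    if not config.adaptive:
        raise ValueError("config.adaptive is False")
    spsnap, nsnap, times = _snapshot_plan(config)
    if spsnap % config.eta and config.eta % spsnap:
        # checks and snapshots must interleave on a common step grid
        raise ValueError(
            f"snapshot_interval/dt = {spsnap} and eta = {config.eta} do not nest"
        )
    base_partition = build_partition(config)
    state0 = make_initial_condition(config, base_partition)
    B = len(output_bins(config))
    total_steps = spsnap * nsnap

    density = np.empty((config.repeats, nsnap + 1, B))
    mass = np.empty((config.repeats, nsnap + 1))
    overlap_cover = np.zeros((nsnap + 1, B), dtype=bool)
    history: list[list[tuple[float, float, str]]] = []
    diag_all = np.zeros(6)
    max_move_mass_change = 0.0
    n_moves = 0
    problem = pde_problem_for(config)

    def _operator(partition: DomainPartition) -> ThetaOperator:
        return ThetaOperator(problem, len(partition.pde_nodes), config.dxp, config.dt)

    for rep in range(config.repeats):
        partition = base_partition
        state = state0.copy()
        kargs = _kernel_args(config, partition, _operator(partition))
        diag = np.zeros(6)
        _kernels.seed_rng(config.seed + rep)
        moves: list[tuple[float, float, str]] = []
        density[rep, 0] = binned_density(state, partition, config.overlap_output)
        mass[rep, 0] = total_mass(state, partition)
        _mark_overlap(overlap_cover, 0, partition, config)
        steps_done = 0
        next_check = config.eta
        for s in range(1, nsnap + 1):
            target = s * spsnap
            while steps_done < target:
                run = min(next_check, target) - steps_done
                if run > 0:
                    _kernels.hybrid_chunk(state.A, state.u, run, diag=diag, **kargs)
                    _check_diag(diag, rep)
                    steps_done += run
                if steps_done == next_check:
                    direction = check_move(state, config, partition)
                    if direction != NONE:
                        m_before = total_mass(state, partition)
                        state2, part2 = move_interface(state, partition, direction)
                        if part2 is not partition:
                            dm = abs(total_mass(state2, part2) - m_before)
                            max_move_mass_change = max(max_move_mass_change, dm)
                            n_moves += 1
                            state, partition = state2, part2
                            kargs = _kernel_args(
                                config, partition, _operator(partition)
                            )
                            moves.append(
                                (steps_done * config.dt, partition.I0, direction)
                            )
                    next_check += config.eta
            state.t = times[s]
            density[rep, s] = binned_density(state, partition, config.overlap_output)
            mass[rep, s] = total_mass(state, partition)
            _mark_overlap(overlap_cover, s, partition, config)
        history.append(moves)
        diag_all[0] = max(diag_all[0], diag[0])
        diag_all[1] += diag[1]
        diag_all[2] += diag[2]
        diag_all[3] += diag[3]
        diag_all[5] = max(diag_all[5], diag[5])

    regime = np.array(["adaptive"] * B)
    return Trajectory(
        times=times,
        x_centres=output_bins(config),
        density=density,
        mass=mass,
        regime=regime,
        config=config,
        mode="hybrid-adaptive",
        diagnostics={
            "max_alpha0_dt": float(diag_all[0]),
            "skipped_removals": float(diag_all[1]),
            "events": float(diag_all[2]),
            "interface_transfers": float(diag_all[3]),
            "max_abs_psi": float(diag_all[5]),
            "interface_moves": n_moves,
            "max_move_mass_change": float(max_move_mass_change),
        },
        interface_history=history,
        overlap_cover=overlap_cover,
    )


def _mark_overlap(
    cover: np.ndarray, s: int, partition: DomainPartition, config: SimulationConfig
) -> None:
    b0 = int(round((partition.I0 - config.domain_lo) / config.h))
    b1 = int(round((partition.I1 - config.domain_lo) / config.h))
    cover[s, b0:b1] = True
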