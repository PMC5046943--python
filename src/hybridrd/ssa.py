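"""Compartment-based stochastic (RDME) dynamics.

Particles hop between neighbouring compartments of width ``h`` at rate
``d = D/h²`` per particle per direction (zero flux at the domain ends:
boundary compartments have one neighbour) and react within
compartments.  Dynamics are *time driven*: each fixed step ``dt``
carries at most one event, accepted with probability ``alpha0*dt``
(so ``alpha0*dt`` must be small; runs warn above 0.1 and refuse at 1).

This module provides both the per-step operations used throughout the
tests (:func:`compute_propensities`, :func:`execute_event`,
:func:`ssa_time_step`) and the fully stochastic reference simulator
:func:`run_fully_stochastic`, whose inner loop is compiled
(:mod:`hybridrd._kernels`) and statistically identical to repeated
:func:`ssa_time_step` calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from .core import (
    ReactionSpec,
    SimulationConfig,
    Trajectory,
    initial_counts_on_grid,
    _require_integer,
)

__all__ = [
    "PropensityTable",
    "Event",
    "compute_propensities",
    "execute_event",
    "ssa_time_step",
    "run_fully_stochastic",
]


class Event(NamedTuple):
    """One executable event: ``kind`` is ``jump_left``/``jump_right`` or a
    reaction-channel label; ``index`` the compartment; ``delta`` the count
    change there; ``target`` the receiving compartment for jumps."""

    kind: str
    index: int
    delta: int
    target: int | None = None


@dataclass(frozen=True)
class PropensityTable:
    """Per-compartment propensities of every channel, plus their total."""

    jump_left: np.ndarray
    jump_right: np.ndarray
    reactions: tuple[tuple[str, int, np.ndarray], ...]  # (label, delta, rates)

    @property
    def alpha0(self) -> float:
        tot = self.jump_left.sum() + self.jump_right.sum()
        for _, _, rates in self.reactions:
            tot += rates.sum()
        return float(tot)

    def flat(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Concatenated rates and the (kind, delta) descriptor per block."""
        blocks = [self.jump_left, self.jump_right]
        kinds = [("jump_left", -1), ("jump_right", -1)]
        for label, delta, rates in self.reactions:
            blocks.append(rates)
            kinds.append((label, delta))
        return np.concatenate(blocks), kinds


def compute_propensities(
    A: np.ndarray, D: float, h: float, spec: ReactionSpec
) -> PropensityTable:
    """Propensity of every jump and reaction channel for counts ``A``."""
    A = np.asarray(A)
    if np.any(A < 0):
        raise ValueError("negative compartment counts")
    d = D / h**2
    jump_left = d * A.astype(float)
    jump_left[0] = 0.0  # zero-flux: no neighbour to the left
    jump_right = d * A.astype(float)
    jump_right[-1] = 0.0
    reactions = tuple(
        (ch.label, ch.delta, np.asarray(ch.propensity(A, h), dtype=float))
        for ch in spec.channels
    )
    return PropensityTable(jump_left, jump_right, reactions)


def execute_event(A: np.ndarray, event: Event) -> np.ndarray:
    """Apply one event's stoichiometry, returning a new count vector."""
    A = np.asarray(A).copy()
    if event.delta < 0 and A[event.index] < -event.delta:
        raise RuntimeError(
            f"event {event.kind} would drive compartment {event.index} below zero "
            f"(count {A[event.index]}); its propensity should have been 0"
        )
    A[event.index] += event.delta
    if event.target is not None:
        A[event.target] += 1
    return A


def select_event(table: PropensityTable, r3: float) -> Event | None:
    """Map a uniform draw to the channel whose cumulative propensity
    bracket contains ``r3 * alpha0``."""
    rates, kinds = table.flat()
    cum = np.cumsum(rates)
    alpha0 = cum[-1]
    if alpha0 <= 0:
        return None
    flat_idx = int(np.searchsorted(cum, r3 * alpha0, side="right"))
    flat_idx = min(flat_idx, len(rates) - 1)
    C = len(table.jump_left)
    block, k = divmod(flat_idx, C)
    kind, delta = kinds[block]
    if kind == "jump_left":
        return Event(kind, k, -1, k - 1)
    if kind == "jump_right":
        return Event(kind, k, -1, k + 1)
    return Event(kind, k, delta)


def ssa_time_step(
    A: np.ndarray,
    dt: float,
    D: float,
    h: float,
    spec: ReactionSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One fixed time step: with probability ``alpha0*dt`` exactly one
    event occurs, chosen proportionally to its propensity."""
    table = compute_propensities(A, D, h, spec)
    alpha0 = table.alpha0
    p = alpha0 * dt
    if p >= 1.0:
        raise RuntimeError(
            f"alpha0*dt = {p:.3g} >= 1: the single-event-per-step probability "
            "interpretation is broken; reduce dt"
        )
    if p > 0.1:
        warnings.warn(
            f"alpha0*dt = {p:.3g} > 0.1: more than one event per step is no "
            "longer rare; consider a smaller dt",
            stacklevel=2,
        )
    if rng.random() < p:
        event = select_event(table, rng.random())
        if event is not None:
            return execute_event(A, event)
    return np.asarray(A).copy()


# ---------------------------------------------------------------------------
# fully stochastic reference simulator


def _kernel_reaction_params(
    config: SimulationConfig, n_compartments: int, stochastic: bool
) -> tuple[float, float, float, float, int]:
    """(mu, k1, k2/h, J, source) for the compiled kernels."""
    mu = k1 = k2oh = J = 0.0
    src = -1
    if config.reaction == "decay":
        mu = config.mu
    elif config.reaction == "morphogen":
        mu = config.mu
        if stochastic:  # production at x = domain_hi lands in the last compartment
            J = config.J
            src = n_compartments - 1
    elif config.reaction == "fisher":
        k1 = config.k1
        k2oh = config.k2 / config.h
    return mu, k1, k2oh, J, src


def _snapshot_plan(config: SimulationConfig) -> tuple[int, int, np.ndarray]:
    """(steps_per_snapshot, n_snapshots, times) for the configured grid."""
    spsnap = _require_integer(config.snapshot_interval / config.dt,
                              "snapshot_interval/dt")
    nsnap = _require_integer(config.T_final / config.snapshot_interval,
                             "T_final/snapshot_interval")
    times = config.snapshot_interval * np.arange(nsnap + 1)
    return spsnap, nsnap, times


def run_fully_stochastic(config: SimulationConfig) -> Trajectory:
    """Simulate the whole domain with the compartment-based model.

    Compartments of width ``h`` tile all of Ω; snapshots are recorded
    every ``snapshot_interval``.  Repeat ``r`` uses RNG stream
    ``seed + r``, so runs are reproducible and repeats independent.
    """
    h = config.h
    C = _require_integer((config.domain_hi - config.domain_lo) / h,
                         "(domain_hi-domain_lo)/h")
    edges = config.domain_lo + h * np.arange(C + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    A0 = initial_counts_on_grid(config, edges)
    d = config.D / h**2
    mu, k1, k2oh, J, src = _kernel_reaction_params(config, C, stochastic=True)
    spsnap, nsnap, times = _snapshot_plan(config)

    density = np.empty((config.repeats, nsnap + 1, C))
    mass = np.empty((config.repeats, nsnap + 1))
    out = np.empty((nsnap, C), dtype=np.int64)
    max_adt = 0.0
    n_events = 0.0
    for rep in range(config.repeats):
        A = A0.copy()
        diag = np.zeros(6)
        _kernels.seed_rng(config.seed + rep)
        _kernels.ssa_run(A, spsnap * nsnap, spsnap, d, config.dt,
                         mu, k1, k2oh, J, src, out, diag)
        if diag[4] == _kernels.ERR_ALPHA:
            raise RuntimeError(
                f"alpha0*dt reached {diag[0]:.3g} >= 1 in repeat {rep}; reduce dt"
            )
        density[rep, 0] = A0 / h
        density[rep, 1:] = out / h
        mass[rep, 0] = A0.sum()
        mass[rep, 1:] = out.sum(axis=1)
        max_adt = max(max_adt, diag[0])
        n_events += diag[2]
    if max_adt > 0.1:
        warnings.warn(
            f"alpha0*dt reached {max_adt:.3g} > 0.1 during the run", stacklevel=2
        )
    return Trajectory(
        times=times,
        x_centres=centres,
        density=density,
        mass=mass,
        regime=np.array(["compartment"] * C),
        config=config,
        mode="stochastic",
        diagnostics={"max_alpha0_dt": float(max_adt), "events": float(n_events)},
    )
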