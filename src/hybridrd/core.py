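"""Domain geometry, configuration and shared state types.

The simulated domain Ω = [domain_lo, domain_hi] is split into a
compartment-based (stochastic, RDME) region Ω_c = [domain_lo, I1] and a
PDE-based (deterministic) region Ω_p = [I0, domain_hi].  The two regions
share an *overlap* [I0, I1] of ``m`` compartments in which both
descriptions are maintained simultaneously.  Compartments have uniform
width ``h``; the PDE is discretised on a uniform mesh of spacing
``dxp`` with one node lying exactly on each interface.

Compartment ``k`` (0-based, left to right) occupies the half-open
interval ``[edge_k, edge_{k+1})``.  Interface-local quantities used by
the coupling refer to the last compartment (index ``C-1``, adjacent to
I1) and the pair straddling I0 (indices ``n-1`` and ``n``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "DomainPartition",
    "HybridState",
    "ReactionSpec",
    "Trajectory",
    "build_partition",
    "make_initial_condition",
    "largest_remainder",
]

logger = logging.getLogger(__name__)

_IC_NAMES = ("uniform", "step_right", "step_left", "fisher_step")
_REACTIONS = ("none", "decay", "morphogen", "fisher")

#: tolerance for "lands on a grid point" checks on derived integers
_ALIGN_TOL = 1e-9


class AlignmentError(ValueError):
    """Interfaces or domain edges do not align with the grids."""


@dataclass
class SimulationConfig:
    """Complete description of one simulation study.

    Parameters
    ----------
    domain_lo, domain_hi
        End points of the full domain Ω (dimensionless length).
    D
        Diffusion coefficient (length²/time).
    dt
        Time step of the coupled algorithm (time).  Must be chosen so
        that the total event propensity satisfies ``alpha0 * dt << 1``
        (single-event regime); the runners warn above 0.1 and refuse
        at >= 1.
    h
        Compartment width (length).
    dxp
        PDE mesh spacing (length).
    I0, I1
        Left/right interfaces of the overlap region.  I0 carries the
        Dirichlet (concentration-matching) condition on the PDE, I1 the
        flux condition on the compartments.
    T_final
        End time of the simulation.
    N
        Initial total particle count (used by the count-based initial
        conditions and by the normalised error metric).
    reaction
        One of ``none`` (pure diffusion), ``decay`` (first-order decay
        at rate ``mu``), ``morphogen`` (decay ``mu`` everywhere plus
        production at rate ``J`` at the right domain edge) or
        ``fisher`` (logistic kinetics ``k1 u - k2 u²``; stochastically
        A→2A at rate k1 and A+A→A at pair rate k2/h per pair).
    mu, J, k1, k2
        Reaction parameters (1/time; particles/time; 1/time;
        length/(particles·time) -- k2 multiplies a squared density).
    repeats
        Number of ensemble repeats.
    seed
        Base RNG seed; repeat ``r`` uses stream ``seed + r``.
    ic_name
        Initial condition: ``uniform``, ``step_right`` (all mass in
        [0, 1]), ``step_left`` (all mass in [-1, 0]) or ``fisher_step``
        (density k1/k2 on the PDE side of ``front_position``).
    adaptive, u_max, delta_u, eta
        Adaptive-interface switch: when the near-interface density (in
        particles per compartment) exceeds ``u_max`` the interfaces move
        one compartment toward the stochastic region; when it falls
        below ``u_max - delta_u`` they move back.  Checked every ``eta``
        steps.
    """

    domain_lo: float = -1.0
    domain_hi: float = 1.0
    D: float = 0.025
    dt: float = 1e-5
    h: float = 0.05
    dxp: float = 0.01
    I0: float = 0.0
    I1: float = 0.1
    T_final: float = 10.0
    N: int = 1000
    reaction: str = "none"
    mu: float = 0.0
    J: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    repeats: int = 100
    seed: int = 0
    ic_name: str = "uniform"
    front_position: float | None = None
    adaptive: bool = False
    u_max: float = 0.0
    delta_u: float = 0.0
    eta: int = 50
    # numerical knobs
    theta: float = 0.5
    snapshot_interval: float = 0.1
    n_sub: int = 1
    dirichlet_one_sided: bool = False
    overlap_output: str = "compartment"  # or "average"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        def _positive(name: str) -> None:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

        for name in ("dt", "h", "dxp", "T_final", "snapshot_interval"):
            _positive(name)
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D!r}")
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N!r}")
        if not (self.domain_lo < self.I0 < self.I1 < self.domain_hi):
            raise ValueError(
                "interfaces must satisfy domain_lo < I0 < I1 < domain_hi, got "
                f"domain_lo={self.domain_lo}, I0={self.I0}, I1={self.I1}, "
                f"domain_hi={self.domain_hi}"
            )
        for name, span in (
            ("m = (I1-I0)/h", self.I1 - self.I0),
            ("n = (I0-domain_lo)/h", self.I0 - self.domain_lo),
        ):
            _require_integer(span / self.h, name)
        for name, span in (
            ("(I1-I0)/dxp", self.I1 - self.I0),
            ("(domain_hi-I0)/dxp", self.domain_hi - self.I0),
        ):
            _require_integer(span / self.dxp, name)
        _require_integer(self.h / self.dxp, "w = h/dxp")
        if self.ic_name not in _IC_NAMES:
            raise ValueError(
                f"unknown ic_name {self.ic_name!r}; expected one of {_IC_NAMES}"
            )
        if self.reaction not in _REACTIONS:
            raise ValueError(
                f"unknown reaction {self.reaction!r}; expected one of {_REACTIONS}"
            )
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")
        if self.adaptive:
            if self.u_max <= 0:
                raise ValueError("adaptive runs need u_max > 0 (particles per compartment)")
            if self.delta_u < 0:
                raise ValueError("delta_u must be >= 0")
            if self.eta < 1:
                raise ValueError("eta must be a positive number of steps")
        if self.overlap_output not in ("compartment", "average"):
            raise ValueError("overlap_output must be 'compartment' or 'average'")

    # convenience
    def with_(self, **kw) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kw)


def _require_integer(x: float, name: str) -> int:
    k = round(x)
    if abs(x - k) > _ALIGN_TOL * max(1.0, abs(x)):
        raise AlignmentError(
            f"{name} must be an integer for the grids to align, got {x!r}"
        )
    return int(k)


@dataclass(frozen=True)
class DomainPartition:
    """Geometry of the split domain: compartment grid, PDE mesh, interfaces.

    ``compartment_edges`` tile [domain_lo, I1]; ``pde_nodes`` span
    [I0, domain_hi] with ``pde_nodes[l]`` lying exactly on I1.
    ``overlap_index_start`` (= n) is the index of the first overlap
    compartment; the overlap compartments are ``n .. C-1`` and the last
    one (index C-1) is adjacent to I1.
    """

    compartment_edges: np.ndarray
    compartment_centres: np.ndarray
    pde_nodes: np.ndarray
    overlap_index_start: int
    w: int
    l: int
    h: float
    dxp: float

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_centres)

    @property
    def n(self) -> int:
        """Compartments strictly left of I0."""
        return self.overlap_index_start

    @property
    def m(self) -> int:
        """Compartments in the overlap [I0, I1]."""
        return self.n_compartments - self.overlap_index_start

    @property
    def I0(self) -> float:
        return float(self.pde_nodes[0])

    @property
    def I1(self) -> float:
        return float(self.pde_nodes[self.l])

    @property
    def domain_lo(self) -> float:
        return float(self.compartment_edges[0])

    @property
    def domain_hi(self) -> float:
        return float(self.pde_nodes[-1])

    def interface_label_map(self) -> dict[int, int]:
        """Translation between internal 0-based indices and the signed
        interface-relative labels common in the hybrid-method literature
        (overlap compartments -1..-m counted leftward from I1, bulk
        compartments 1..n counted leftward from I0)."""
        C, n = self.n_compartments, self.overlap_index_start
        table = {}
        for idx in range(C):
            if idx >= n:
                # overlap counts -1..-m rightward from I0; index C-1
                # (adjacent to I1) carries label -m
                table[idx] = -(idx - n + 1)
            else:
                table[idx] = idx + 1
        return table


def build_partition(config: SimulationConfig) -> DomainPartition:
    """Construct the compartment grid and PDE mesh for ``config``.

    Raises :class:`AlignmentError` when I0/I1 do not align with the
    compartment or PDE grids (non-integer m, n or w).
    """
    h, dxp = config.h, config.dxp
    m = _require_integer((config.I1 - config.I0) / h, "m = (I1-I0)/h")
    n = _require_integer((config.I0 - config.domain_lo) / h, "n = (I0-domain_lo)/h")
    w = _require_integer(h / dxp, "w = h/dxp")
    K = _require_integer((config.domain_hi - config.I0) / dxp, "(domain_hi-I0)/dxp")
    if m < 1 or n < 1:
        raise AlignmentError(f"need at least one compartment on each side of I0 (m={m}, n={n})")
    C = n + m
    edges = config.domain_lo + h * np.arange(C + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    nodes = config.I0 + dxp * np.arange(K + 1)
    l = m * w
    # ghost compartment centre I1 + h/2 must lie inside the PDE mesh
    if config.I1 + h / 2 > config.domain_hi + _ALIGN_TOL:
        raise AlignmentError(
            f"ghost compartment centre I1 + h/2 = {config.I1 + h / 2} lies outside "
            f"the PDE region (domain_hi = {config.domain_hi})"
        )
    part = DomainPartition(
        compartment_edges=edges,
        compartment_centres=centres,
        pde_nodes=nodes,
        overlap_index_start=n,
        w=w,
        l=l,
        h=h,
        dxp=dxp,
    )
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("compartment index translation table: %s", part.interface_label_map())
    return part


@dataclass
class HybridState:
    """The single evolving object: integer counts + PDE density + clock.

    ``A[k]`` is the particle count of compartment ``k`` (particles);
    ``u[i]`` the PDE density at node ``i`` (particles/length).  The
    probability-density views used in single-particle arguments are
    ``A/(N h)`` and ``u/N``.
    """

    A: np.ndarray
    u: np.ndarray
    t: float = 0.0

    def copy(self) -> "HybridState":
        return HybridState(self.A.copy(), self.u.copy(), self.t)

    def prob_compartment(self, N: int, h: float) -> np.ndarray:
        return self.A / (N * h)

    def prob_pde(self, N: int) -> np.ndarray:
        return self.u / N


@dataclass(frozen=True)
class ReactionChannel:
    label: str
    delta: int  # count change in the affected compartment

    def propensity(self, A: np.ndarray, h: float) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class DecayChannel(ReactionChannel):
    mu: float = 0.0

    def propensity(self, A: np.ndarray, h: float) -> np.ndarray:
        return self.mu * A


@dataclass(frozen=True)
class ProductionChannel(ReactionChannel):
    """Zeroth-order production at rate J into a single source compartment."""

    J: float = 0.0
    source: int = -1

    def propensity(self, A: np.ndarray, h: float) -> np.ndarray:
        out = np.zeros(len(A))
        out[self.source] = self.J
        return out


@dataclass(frozen=True)
class BirthChannel(ReactionChannel):
    k1: float = 0.0

    def propensity(self, A: np.ndarray, h: float) -> np.ndarray:
        return self.k1 * A


@dataclass(frozen=True)
class PairDeathChannel(ReactionChannel):
    """A + A -> A with mesoscopic rate (k2/h)·A(A-1), the RDME form whose
    mean field recovers the -k2 u² sink of the logistic equation."""

    k2: float = 0.0

    def propensity(self, A: np.ndarray, h: float) -> np.ndarray:
        return (self.k2 / h) * A * (A - 1.0)


@dataclass(frozen=True)
class ReactionSpec:
    """Set of per-compartment reaction channels (diffusion jumps excluded)."""

    channels: tuple[ReactionChannel, ...] = ()

    @classmethod
    def none(cls) -> "ReactionSpec":
        return cls(())

    @classmethod
    def decay(cls, mu: float) -> "ReactionSpec":
        return cls((DecayChannel("decay", -1, mu),))

    @classmethod
    def morphogen(cls, mu: float, J: float, source: int) -> "ReactionSpec":
        return cls(
            (
                DecayChannel("decay", -1, mu),
                ProductionChannel("production", +1, J, source),
            )
        )

    @classmethod
    def fisher(cls, k1: float, k2: float) -> "ReactionSpec":
        return cls(
            (
                BirthChannel("birth", +1, k1),
                PairDeathChannel("pair_death", -1, k2),
            )
        )

    @classmethod
    def for_config(cls, config: SimulationConfig, *, stochastic_source: int | None = None) -> "ReactionSpec":
        """Channels acting in the compartment region for ``config``.

        For the morphogen problem the production boundary (x = domain_hi)
        lies in the PDE region of a hybrid run, so production only becomes
        a stochastic channel when ``stochastic_source`` names the source
        compartment (fully stochastic runs)."""
        if config.reaction == "none":
            return cls.none()
        if config.reaction == "decay":
            return cls.decay(config.mu)
        if config.reaction == "morphogen":
            if stochastic_source is None:
                return cls.decay(config.mu)
            return cls.morphogen(config.mu, config.J, stochastic_source)
        if config.reaction == "fisher":
            return cls.fisher(config.k1, config.k2)
        raise ValueError(config.reaction)


# ---------------------------------------------------------------------------
# initial conditions


def largest_remainder(quotas: np.ndarray, total: int | None = None) -> np.ndarray:
    """Apportion integer counts to real-valued quotas.

    Each entry gets ``floor(quota)``; the remaining units (to reach
    ``total``, default ``round(sum(quotas))``) go to the largest
    fractional remainders.  Exact when the quotas are integers.
    """
    quotas = np.asarray(quotas, dtype=float)
    if np.any(quotas < -1e-12):
        raise ValueError("quotas must be nonnegative")
    quotas = np.clip(quotas, 0.0, None)
    if total is None:
        total = int(round(quotas.sum()))
    base = np.floor(quotas + 1e-12).astype(np.int64)
    short = int(total - base.sum())
    if short < 0:
        # quotas summed above total (can happen after clipping); trim from
        # the smallest remainders
        order = np.argsort(quotas - base)
        for i in order[: -short]:
            if base[i] > 0:
                base[i] -= 1
        return base
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    return base


def make_initial_condition(
    config: SimulationConfig, partition: DomainPartition
) -> HybridState:
    """Build a hybrid state consistent across both representations.

    The compartment counts and PDE density agree in the overlap (node
    density equals the local compartment density), and the total system
    mass equals N for the count-based initial conditions (up to the
    integer apportionment of compartment counts).
    """
    C = partition.n_compartments
    x_nodes = partition.pde_nodes
    centres = partition.compartment_centres
    h = partition.h
    lo, hi = partition.domain_lo, partition.domain_hi
    I1 = partition.I1

    if config.ic_name == "uniform":
        rho = config.N / (hi - lo)
        u = np.full(len(x_nodes), rho)
        # compartments carry the mass of [lo, I1]; the PDE owns (I1, hi]
        target = config.N - rho * (hi - I1)
        A = largest_remainder(np.full(C, rho * h), int(round(target)))
    elif config.ic_name in ("step_right", "step_left"):
        # all mass uniformly on [0, 1] (step_right) or [-1, 0] (step_left);
        # these ICs presume the canonical domain [-1, 1]
        if config.ic_name == "step_right":
            a, b = 0.0, 1.0
        else:
            a, b = -1.0, 0.0
        rho = config.N / (b - a)
        u = np.where((x_nodes >= a - 1e-12) & (x_nodes <= b + 1e-12), rho, 0.0)
        if b <= config.I0 + 1e-12:
            # mass region entirely on the compartment side: at the I0 node
            # the PDE-side limit of the density is zero
            u[:] = 0.0
        quotas = rho * np.clip(
            np.minimum(partition.compartment_edges[1:], b)
            - np.maximum(partition.compartment_edges[:-1], a),
            0.0,
            None,
        )
        pde_only_mass = float(np.trapezoid(u, x_nodes)) - float(
            np.trapezoid(u[: partition.l + 1], x_nodes[: partition.l + 1])
        )
        A = largest_remainder(quotas, int(round(config.N - pde_only_mass)))
    elif config.ic_name == "fisher_step":
        if config.k2 <= 0:
            raise ValueError("fisher_step needs k1, k2 > 0")
        front = config.I0 if config.front_position is None else config.front_position
        plateau = config.k1 / config.k2
        u = np.where(x_nodes >= front - 1e-12, plateau, 0.0)
        quotas = np.where(centres >= front, plateau * h, 0.0)
        A = largest_remainder(quotas)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown ic_name {config.ic_name!r}")

    return HybridState(A=A.astype(np.int64), u=u.astype(float), t=0.0)


def initial_density_pieces(config: SimulationConfig) -> list[tuple[float, float, float]]:
    """The initial condition as piecewise-constant (x0, x1, density) pieces."""
    lo, hi = config.domain_lo, config.domain_hi
    if config.ic_name == "uniform":
        return [(lo, hi, config.N / (hi - lo))]
    if config.ic_name == "step_right":
        return [(0.0, 1.0, float(config.N))]
    if config.ic_name == "step_left":
        return [(-1.0, 0.0, float(config.N))]
    if config.ic_name == "fisher_step":
        if config.k2 <= 0:
            raise ValueError("fisher_step needs k1, k2 > 0")
        front = config.I0 if config.front_position is None else config.front_position
        return [(front, hi, config.k1 / config.k2)]
    raise ValueError(f"unknown ic_name {config.ic_name!r}")


def initial_density_at(config: SimulationConfig, x: np.ndarray) -> np.ndarray:
    """Initial density sampled at positions ``x`` (piece endpoints inclusive)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for x0, x1, rho in initial_density_pieces(config):
        out = np.where((x >= x0 - 1e-12) & (x <= x1 + 1e-12), rho, out)
    return out


def initial_counts_on_grid(config: SimulationConfig, edges: np.ndarray) -> np.ndarray:
    """Integer counts apportioning the initial mass to compartments with the
    given edges (largest-remainder rounding; exact totals when possible)."""
    quotas = np.zeros(len(edges) - 1)
    for x0, x1, rho in initial_density_pieces(config):
        overlap = np.clip(
            np.minimum(edges[1:], x1) - np.maximum(edges[:-1], x0), 0.0, None
        )
        quotas += rho * overlap
    return largest_remainder(quotas)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Ensemble of recorded density snapshots on the width-h output grid.

    ``density[r, s, b]`` is the binned particle density of repeat ``r``
    at ``times[s]`` in bin ``b`` (bins of width h tiling the full
    domain).  ``mass[r, s]`` is the total particle mass at the snapshot
    (compartments own the overlap; the PDE region is integrated with the
    trapezoidal rule).  ``regime`` labels each bin of the *initial*
    partition as ``compartment``, ``overlap`` or ``pde``; for adaptive
    runs ``interface_history`` records (time, I0) per repeat and
    ``overlap_cover[s, b]`` flags bins that were inside the overlap of
    any repeat at snapshot ``s``.
    """

    times: np.ndarray
    x_centres: np.ndarray
    density: np.ndarray
    mass: np.ndarray
    regime: np.ndarray
    config: SimulationConfig
    mode: str = "hybrid"
    diagnostics: dict = field(default_factory=dict)
    interface_history: list | None = None
    overlap_cover: np.ndarray | None = None

    @property
    def repeats(self) -> int:
        return self.density.shape[0]

    def mean_density(self) -> np.ndarray:
        return self.density.mean(axis=0)

    def mean_mass(self) -> np.ndarray:
        return self.mass.mean(axis=0)


def output_bins(config: SimulationConfig) -> np.ndarray:
    """Centres of the width-h output grid tiling the full domain."""
    B = _require_integer((config.domain_hi - config.domain_lo) / config.h,
                         "(domain_hi-domain_lo)/h")
    return config.domain_lo + config.h * (np.arange(B) + 0.5)
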