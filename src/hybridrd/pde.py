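"""Finite-difference solution of the deterministic reaction-diffusion PDE.

The θ-scheme (default θ = 1/2, Crank–Nicolson) discretises

    ∂u/∂t = D ∂²u/∂x² + R(u)

on a uniform mesh.  Diffusion is treated θ-implicitly; the reaction
term R (decay −μu or logistic k₁u − k₂u²) is treated explicitly (IMEX),
which avoids a nonlinear solve and is accurate at the small steps the
hybrid algorithm requires anyway.  Boundary conditions:

* left: a Dirichlet value supplied per step (hybrid coupling mode) or
  zero flux (standalone mode);
* right: zero flux, or a particle influx J (−D ∂u/∂x = J inward),
  both via second-order ghost-node reflection.

The linear solve uses a Thomas (tridiagonal) factorisation computed
once per operator, so repeated steps only forward/back substitute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "PDEProblem",
    "ThetaOperator",
    "pde_step",
    "analytic_diffusion_solution",
    "morphogen_steady_state",
]


@dataclass(frozen=True)
class PDEProblem:
    """Physics of the PDE half of the model.

    ``reaction``: ``none`` | ``decay`` | ``logistic``;
    ``right_bc``: ``zero_flux`` | ``influx`` (rate J);
    ``left_bc``: ``dirichlet`` (value supplied per step) | ``zero_flux``.
    """

    D: float
    reaction: str = "none"
    mu: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    right_bc: str = "zero_flux"
    J: float = 0.0
    left_bc: str = "dirichlet"
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.reaction not in ("none", "decay", "logistic"):
            raise ValueError(f"unknown reaction {self.reaction!r}")
        if self.right_bc not in ("zero_flux", "influx"):
            raise ValueError(f"unknown right_bc {self.right_bc!r}")
        if self.left_bc not in ("dirichlet", "zero_flux"):
            raise ValueError(f"unknown left_bc {self.left_bc!r}")

    def reaction_rate(self, u: np.ndarray) -> np.ndarray:
        if self.reaction == "decay":
            return -self.mu * u
        if self.reaction == "logistic":
            return self.k1 * u - self.k2 * u * u
        return np.zeros_like(u)


class ThetaOperator:
    """Pre-factorised θ-scheme stepper on a fixed mesh.

    Builds the constant tridiagonal system once; :meth:`step` performs
    one time step (optionally imposing a Dirichlet value at node 0).
    """

    def __init__(self, problem: PDEProblem, n_nodes: int, dxp: float, dt: float):
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        if n_nodes < 3:
            raise ValueError("need at least 3 mesh nodes")
        r = problem.D * dt / dxp**2
        if problem.theta < 0.5:
            limit = 0.5 / (1.0 - 2.0 * problem.theta)
            if r > limit + 1e-12:
                raise ValueError(
                    f"theta-scheme stability violated: D*dt/dxp^2 = {r:.4g} exceeds "
                    f"{limit:.4g} for theta = {problem.theta}"
                )
        self.problem = problem
        self.n = n_nodes
        self.dxp = dxp
        self.dt = dt
        self.r = r
        th = problem.theta
        K = n_nodes - 1

        # tridiagonal (I - theta*r*L), L the second-difference operator with
        # ghost-node reflection at zero-flux boundaries
        sub = np.full(n_nodes, -th * r)
        diag = np.full(n_nodes, 1.0 + 2.0 * th * r)
        sup = np.full(n_nodes, -th * r)
        # right boundary: L u_K = 2 u_{K-1} - 2 u_K (+ influx source handled in rhs)
        sub[K] = -2.0 * th * r
        if problem.left_bc == "dirichlet":
            diag[0] = 1.0
            sup[0] = 0.0
        else:  # zero flux: L u_0 = 2 u_1 - 2 u_0
            sup[0] = -2.0 * th * r
        self._sub, self._diag, self._sup = sub, diag, sup
        # Thomas pre-factorisation
        cp = np.empty(n_nodes)
        bp = np.empty(n_nodes)
        wf = np.empty(n_nodes)
        bp[0] = diag[0]
        cp[0] = sup[0]
        for i in range(1, n_nodes):
            wf[i] = sub[i] / bp[i - 1]
            bp[i] = diag[i] - wf[i] * cp[i - 1]
            cp[i] = sup[i]
        self._wf, self._bp, self._cp = wf, bp, cp
        ab = np.zeros((3, n_nodes))
        ab[0, 1:] = sup[:-1]
        ab[1, :] = diag
        ab[2, :-1] = sub[1:]
        self._ab = ab
        # constant influx contribution to the rhs at node K: the ghost
        # relation u_{K+1} = u_{K-1} + 2 dxp J / D adds r * 2 dxp J / D in
        # total across the explicit and implicit halves
        self._influx_rhs = (
            2.0 * problem.J * dt / dxp if problem.right_bc == "influx" else 0.0
        )

    def rhs(self, u: np.ndarray, dirichlet_value: float | None) -> np.ndarray:
        p, r, th = self.problem, self.r, self.problem.theta
        K = self.n - 1
        d = np.empty_like(u)
        lap = np.empty_like(u)
        lap[1:K] = u[0:K - 1] - 2.0 * u[1:K] + u[2:K + 1]
        lap[K] = 2.0 * (u[K - 1] - u[K])
        lap[0] = 2.0 * (u[1] - u[0])
        d[:] = u + (1.0 - th) * r * lap + self.dt * p.reaction_rate(u)
        d[K] += self._influx_rhs
        if p.left_bc == "dirichlet":
            if dirichlet_value is None:
                raise ValueError("left_bc is 'dirichlet' but no value was supplied")
            d[0] = dirichlet_value
        return d

    def solve(self, d: np.ndarray) -> np.ndarray:
        from scipy.linalg import solve_banded

        return solve_banded((1, 1), self._ab, d)

    def step(self, u: np.ndarray, dirichlet_value: float | None = None) -> np.ndarray:
        return self.solve(self.rhs(np.asarray(u, dtype=float), dirichlet_value))


def pde_step(
    u: np.ndarray,
    problem: PDEProblem,
    dxp: float,
    dt_pde: float,
    dirichlet_value: float | None = None,
) -> np.ndarray:
    """Advance ``u`` by one θ-scheme step of size ``dt_pde``.

    Convenience wrapper building a one-shot :class:`ThetaOperator`;
    loops should construct the operator once and call ``.step``.
    """
    op = ThetaOperator(problem, len(u), dxp, dt_pde)
    return op.step(u, dirichlet_value)


# ---------------------------------------------------------------------------
# reference solutions


def analytic_diffusion_solution(
    x: np.ndarray | float,
    t: float,
    D: float,
    ic_name: str,
    N: float,
    tol: float = 1e-12,
    min_pairs: int = 3,
) -> np.ndarray:
    """Image-series solution of pure diffusion on [-1, 1], zero-flux ends.

    Initial data: ``uniform`` (N/2 everywhere), ``step_right`` (density N
    on [0, 1]) or ``step_left`` (density N on [-1, 0], obtained from
    step_right by x → −x).  Reflections at x = ±1 make the even periodic
    extension of the step a union of intervals [0, 2] + 4k, so

        u(x, t) = (N/2) Σ_k [erf((x − 4k)/s) − erf((x − 2 − 4k)/s)]

    with s = 2√(Dt).  Terms are added outward in k until the added
    pair's magnitude falls below ``tol`` (at least ``min_pairs`` pairs).
    """
    x = np.asarray(x, dtype=float)
    if ic_name == "uniform":
        return np.full_like(x, N / 2.0)
    if ic_name == "step_left":
        return analytic_diffusion_solution(-x, t, D, "step_right", N, tol, min_pairs)
    if ic_name != "step_right":
        raise ValueError(f"no analytic solution for ic_name {ic_name!r}")
    if t <= 0:
        return np.where((x >= 0) & (x <= 1), float(N), 0.0) * np.ones_like(x)
    s = 2.0 * np.sqrt(D * t)

    def term(k: int) -> np.ndarray:
        return 0.5 * N * (erf((x - 4.0 * k) / s) - erf((x - 2.0 - 4.0 * k) / s))

    out = term(0)
    k = 1
    while True:
        add = term(k) + term(-k)
        out += add
        if k >= min_pairs and np.max(np.abs(add)) < tol:
            break
        k += 1
        if k > 10000:  # pragma: no cover - s would have to be astronomically large
            break
    return out


def run_pde(config, dxp: float | None = None, dt: float | None = None):
    """Deterministic PDE solve over the *whole* domain (mean-field model).

    Used standalone (``--mode pde``) and as the deterministic oracle for
    the travelling-wave speed.  Zero flux at both ends unless the config
    declares the morphogen influx.  Returns a single-"repeat"
    :class:`~hybridrd.core.Trajectory` on the width-h output grid.
    """
    from .core import Trajectory, initial_density_at, output_bins, _require_integer

    dxp = config.dxp if dxp is None else dxp
    dt = config.dt if dt is None else dt
    lo, hi = config.domain_lo, config.domain_hi
    K = _require_integer((hi - lo) / dxp, "(domain_hi-domain_lo)/dxp")
    x = lo + dxp * np.arange(K + 1)
    reaction, mu, k1, k2 = "none", 0.0, 0.0, 0.0
    right_bc, J = "zero_flux", 0.0
    if config.reaction == "decay":
        reaction, mu = "decay", config.mu
    elif config.reaction == "morphogen":
        reaction, mu = "decay", config.mu
        right_bc, J = "influx", config.J
    elif config.reaction == "fisher":
        reaction, k1, k2 = "logistic", config.k1, config.k2
    problem = PDEProblem(
        D=config.D, reaction=reaction, mu=mu, k1=k1, k2=k2,
        right_bc=right_bc, J=J, left_bc="zero_flux", theta=config.theta,
    )
    op = ThetaOperator(problem, K + 1, dxp, dt)
    spsnap = _require_integer(config.snapshot_interval / dt, "snapshot_interval/dt")
    nsnap = _require_integer(config.T_final / config.snapshot_interval,
                             "T_final/snapshot_interval")
    times = config.snapshot_interval * np.arange(nsnap + 1)
    u = initial_density_at(config, x)
    centres = output_bins(config)
    w = round(config.h / dxp)
    weights = np.ones(w + 1)
    weights[0] = weights[-1] = 0.5

    def _bin(u_now: np.ndarray) -> np.ndarray:
        return np.array(
            [np.dot(u_now[j * w : j * w + w + 1], weights) / w
             for j in range(len(centres))]
        )

    density = np.empty((1, nsnap + 1, len(centres)))
    mass = np.empty((1, nsnap + 1))
    density[0, 0] = _bin(u)
    mass[0, 0] = np.trapezoid(u, dx=dxp)
    for s in range(1, nsnap + 1):
        for _ in range(spsnap):
            u = op.step(u)
        density[0, s] = _bin(u)
        mass[0, s] = np.trapezoid(u, dx=dxp)
    return Trajectory(
        times=times,
        x_centres=centres,
        density=density,
        mass=mass,
        regime=np.array(["pde"] * len(centres)),
        config=config,
        mode="pde",
    )


def morphogen_steady_state(
    x: np.ndarray | float, D: float, mu: float, J: float
) -> np.ndarray:
    """Steady state of diffusion + decay μ with influx J at x = 1 and zero
    flux at x = −1 on [−1, 1]:

        u_s(x) = J cosh(λ(x+1)) / (√(Dμ) sinh(2λ)),   λ = √(μ/D).

    The global balance ∫ u_s = J/μ (production = decay) holds exactly.
    """
    if D <= 0 or mu <= 0:
        raise ValueError("need D > 0 and mu > 0")
    x = np.asarray(x, dtype=float)
    lam = np.sqrt(mu / D)
    return J * np.cosh(lam * (x + 1.0)) / (np.sqrt(D * mu) * np.sinh(2.0 * lam))
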