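"""Compiled inner loops for the hybrid and fully stochastic simulators.

These kernels implement exactly the same per-step rules as the pure
numpy operations in :mod:`hybridrd.ssa` and :mod:`hybridrd.coupling`
(which the test-suite cross-validates); they exist because the coupled
algorithm takes millions of fixed-size time steps per repeat.

Conventions shared with the rest of the package:

* ``A`` — int64 compartment counts, index 0 at the left domain edge,
  index C-1 adjacent to the interface I1;
* ``u`` — float64 PDE nodal density, node 0 on I0;
* one event at most per step (Bernoulli ``alpha0*dt``), one interface
  transfer at most per step (Bernoulli ``|psi|``);
* diag vector: [0] max alpha0*dt seen, [1] skipped empty removals,
  [2] events executed, [3] interface transfers, [4] error code
  (0 ok, 1 |psi|>=1, 2 alpha0*dt>=1), [5] max |psi| seen.

The RNG is numba's global per-thread MT19937; callers seed it once per
repeat through :func:`seed_rng`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ERR_NONE = 0
ERR_PSI = 1
ERR_ALPHA = 2


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True, inline="always", fastmath=True)
def _alpha0(A, d, mu, k1, k2oh, J_src):
    C = A.shape[0]
    tot = 0.0
    for k in range(C):
        a = float(A[k])
        njump = 2.0
        if k == 0 or k == C - 1:
            njump = 1.0
        tot += d * a * njump + mu * a + k1 * a + k2oh * a * (a - 1.0)
    tot += J_src
    return tot


@njit(cache=True, inline="always")
def _execute(A, target, d, mu, k1, k2oh, J, src):
    """Select the event whose cumulative propensity brackets ``target``
    and apply its stoichiometry.  Channel order per compartment:
    jump-left, jump-right, decay, birth, pair-death; production last."""
    C = A.shape[0]
    acc = 0.0
    for k in range(C):
        a = float(A[k])
        if a > 0.0:
            if k > 0:
                acc += d * a
                if target < acc:
                    A[k] -= 1
                    A[k - 1] += 1
                    return True
            if k < C - 1:
                acc += d * a
                if target < acc:
                    A[k] -= 1
                    A[k + 1] += 1
                    return True
            if mu > 0.0:
                acc += mu * a
                if target < acc:
                    A[k] -= 1
                    return True
            if k1 > 0.0:
                acc += k1 * a
                if target < acc:
                    A[k] += 1
                    return True
            if k2oh > 0.0 and a > 1.0:
                acc += k2oh * a * (a - 1.0)
                if target < acc:
                    A[k] -= 1
                    return True
    if src >= 0 and J > 0.0:
        acc += J
        if target < acc:
            A[src] += 1
            return True
    return False


@njit(cache=True)
def ssa_run(A, total_steps, snap_every, d, dt, mu, k1, k2oh, J, src, out, diag):
    """Fully stochastic run of ``total_steps`` fixed steps.

    Records the state after every ``snap_every`` steps into ``out``
    (shape (total_steps // snap_every, C)).  Between events the state is
    frozen, so the number of empty steps before the next event is drawn
    from the exact geometric distribution of the per-step Bernoulli
    trial instead of looping step by step.
    """
    s = 0
    next_snap = snap_every
    snap_i = 0
    alpha = _alpha0(A, d, mu, k1, k2oh, J if src >= 0 else 0.0)
    while s < total_steps:
        p = alpha * dt
        if p > diag[0]:
            diag[0] = p
        if p >= 1.0:
            diag[4] = ERR_ALPHA
            return
        if p <= 0.0:
            event_step = total_steps + 1
        else:
            r = np.random.random()
            if r <= 0.0:
                event_step = total_steps + 1
            else:
                g = np.log(r) / np.log1p(-p)
                if g > 4.0e18:
                    event_step = total_steps + 1
                else:
                    event_step = s + 1 + int(g)
        while next_snap < event_step and next_snap <= total_steps:
            for c in range(A.shape[0]):
                out[snap_i, c] = A[c]
            snap_i += 1
            next_snap += snap_every
        if event_step > total_steps:
            return
        target = np.random.random() * alpha
        if _execute(A, target, d, mu, k1, k2oh, J, src):
            diag[2] += 1.0
        alpha = _alpha0(A, d, mu, k1, k2oh, J if src >= 0 else 0.0)
        s = event_step
        if next_snap == s:
            for c in range(A.shape[0]):
                out[snap_i, c] = A[c]
            snap_i += 1
            next_snap += snap_every


@njit(cache=True, fastmath=True)
def hybrid_chunk(
    A,
    u,
    nsteps,
    # geometry / coupling
    d,
    dt,
    h,
    D,
    i_mm,
    f_mm,
    i_gh,
    f_gh,
    n_left,
    one_sided,
    # compartment reactions
    mu,
    k1,
    k2oh,
    # theta-scheme prefactors (see pde.ThetaOperator)
    wf,
    inv_bp,
    cp,
    r_mesh,
    theta,
    influx_rhs,
    pde_rx,
    pde_mu,
    pde_k1,
    pde_k2,
    rhs,
    diag,
):
    """Advance the coupled state in place by ``nsteps`` steps.

    Per step, following the time-based coupled algorithm: interface
    transfer at I1 (Bernoulli on the PDE-gradient flux psi), at most one
    stochastic event in the compartment region, then the Dirichlet value
    at I0 is refreshed from the straddling compartments and the PDE is
    advanced one theta-scheme step.
    """
    C = A.shape[0]
    K = u.shape[0] - 1
    alpha = _alpha0(A, d, mu, k1, k2oh, 0.0)
    coeff = D * dt / h  # psi = coeff * (u_ghost - u_mm)
    for _ in range(nsteps):
        # (iii) interface transfer at I1
        u_mm = u[i_mm] * (1.0 - f_mm) + u[i_mm + 1] * f_mm
        u_gh = u[i_gh] * (1.0 - f_gh) + u[i_gh + 1] * f_gh
        psi = coeff * (u_gh - u_mm)
        apsi = abs(psi)
        if apsi > diag[5]:
            diag[5] = apsi
        if apsi >= 1.0:
            diag[4] = ERR_PSI
            return
        r1 = np.random.random()
        if r1 < apsi:
            if psi > 0.0:
                A[C - 1] += 1
                diag[3] += 1.0
                alpha = _alpha0(A, d, mu, k1, k2oh, 0.0)
            elif A[C - 1] > 0:
                A[C - 1] -= 1
                diag[3] += 1.0
                alpha = _alpha0(A, d, mu, k1, k2oh, 0.0)
            else:
                diag[1] += 1.0
        # (iv)-(v) at most one reaction/jump event in the compartments
        p = alpha * dt
        if p > diag[0]:
            diag[0] = p
        if p >= 1.0:
            diag[4] = ERR_ALPHA
            return
        r2 = np.random.random()
        if r2 < p:
            target = np.random.random() * alpha
            if _execute(A, target, d, mu, k1, k2oh, 0.0, -1):
                diag[2] += 1.0
            alpha = _alpha0(A, d, mu, k1, k2oh, 0.0)
        # (vii) Dirichlet matching at I0, then one PDE step; the rhs build
        # is fused with the Thomas forward elimination (left-to-right) and
        # the nonnegativity clip with the back substitution
        if one_sided:
            g = A[n_left] / h
        else:
            g = (A[n_left] + A[n_left + 1]) / (2.0 * h)
        u[0] = g  # concentration matching applied to the state pre-step
        er = (1.0 - theta) * r_mesh
        rhs[0] = g
        for i in range(1, K):
            ui = u[i]
            rx = 0.0
            if pde_rx == 1:
                rx = -pde_mu * ui
            elif pde_rx == 2:
                rx = pde_k1 * ui - pde_k2 * ui * ui
            rhs[i] = (
                ui + er * (u[i - 1] - 2.0 * ui + u[i + 1]) + dt * rx
                - wf[i] * rhs[i - 1]
            )
        uK = u[K]
        rxK = 0.0
        if pde_rx == 1:
            rxK = -pde_mu * uK
        elif pde_rx == 2:
            rxK = pde_k1 * uK - pde_k2 * uK * uK
        rhs[K] = (
            uK + er * 2.0 * (u[K - 1] - uK) + dt * rxK + influx_rhs
            - wf[K] * rhs[K - 1]
        )
        u[K] = rhs[K] * inv_bp[K]
        for i in range(K - 1, -1, -1):
            u[i] = (rhs[i] - cp[i] * u[i + 1]) * inv_bp[i]
        for i in range(K + 1):
            if u[i] < 0.0:
                u[i] = 0.0
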