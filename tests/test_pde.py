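"""Finite-difference solver and closed-form reference solutions."""

import numpy as np
import pytest
from scipy.linalg import solve_banded

import hybridrd as hr
from hybridrd.pde import PDEProblem, ThetaOperator, analytic_diffusion_solution


def _operator(problem, n, dxp, dt):
    return ThetaOperator(problem, n, dxp, dt)


def test_uniform_field_is_steady_state():
    u = np.full(51, 7.3)
    op = _operator(PDEProblem(D=0.025, left_bc="zero_flux"), 51, 0.02, 1e-3)
    out = op.step(u)
    assert np.allclose(out, 7.3, atol=1e-12)


def _cosine_error(dxp, dt, t=1.0, D=0.025):
    x = np.arange(0.0, 1.0 + 1e-12, dxp)
    u = np.cos(np.pi * x)
    op = _operator(PDEProblem(D=D, left_bc="zero_flux"), len(x), dxp, dt)
    for _ in range(int(round(t / dt))):
        u = op.step(u)
    exact = np.cos(np.pi * x) * np.exp(-D * np.pi**2 * t)
    return np.max(np.abs(u - exact))


def test_cosine_eigenmode_accuracy():
    # second-order scheme: well below 1e-4 at dxp=0.01, dt=1e-3
    assert _cosine_error(0.01, 1e-3) < 1e-4


def test_crank_nicolson_convergence_order():
    e_coarse = _cosine_error(0.02, 4e-3)
    e_fine = _cosine_error(0.01, 2e-3)
    order = np.log2(e_coarse / e_fine)
    assert order >= 1.8


def test_explicit_scheme_stability_guard():
    with pytest.raises(ValueError, match="stability"):
        _operator(PDEProblem(D=1.0, theta=0.0), 51, 0.02, 1e-3)  # r = 2.5
    # same r is fine for the unconditionally stable default
    _operator(PDEProblem(D=1.0, theta=0.5), 51, 0.02, 1e-3)


def test_decay_reaction_matches_ode():
    dt = 1e-3
    u = np.full(21, 4.0)
    op = _operator(
        PDEProblem(D=0.025, reaction="decay", mu=0.2, left_bc="zero_flux"),
        21, 0.05, dt,
    )
    out = op.step(u)
    # explicit reaction: error is O((mu*dt)^2) against exp(-mu*dt)
    assert np.allclose(out, 4.0 * np.exp(-0.2 * dt), atol=1e-6)


def test_mass_conservation_zero_flux():
    dxp, dt = 0.01, 1e-3
    x = np.arange(-1.0, 1.0 + 1e-12, dxp)
    u = 500.0 * (1.0 + 0.5 * np.sin(2 * np.pi * x))
    m0 = np.trapezoid(u, dx=dxp)
    op = _operator(PDEProblem(D=0.025, left_bc="zero_flux"), len(x), dxp, dt)
    for _ in range(1000):
        u = op.step(u)
    assert abs(np.trapezoid(u, dx=dxp) - m0) / m0 < 1e-10


def test_influx_boundary_adds_mass_at_rate_J():
    dxp, dt, J = 0.01, 1e-3, 125.0
    x = np.arange(0.0, 1.0 + 1e-12, dxp)
    u = np.zeros_like(x)
    op = _operator(
        PDEProblem(D=0.05, right_bc="influx", J=J, left_bc="zero_flux"),
        len(x), dxp, dt,
    )
    for _ in range(200):
        u = op.step(u)
    assert np.trapezoid(u, dx=dxp) == pytest.approx(J * 200 * dt, rel=1e-10)


# -- analytic diffusion solution -------------------------------------------


def _spectral(x, t, D, N, terms=400):
    """Independent cosine-series oracle for the zero-flux step problem."""
    x = np.asarray(x, dtype=float)
    u = np.full_like(x, 0.5)
    for j in range(1, terms):
        aj = -(2.0 / (j * np.pi)) * np.sin(j * np.pi / 2)
        u = u + aj * np.cos(j * np.pi * (x + 1) / 2) * np.exp(
            -D * (j * np.pi / 2) ** 2 * t
        )
    return N * u


@pytest.mark.parametrize("t", [0.05, 0.5, 5.0, 50.0])
def test_image_series_matches_spectral_oracle(t):
    x = np.linspace(-1, 1, 41)
    img = analytic_diffusion_solution(x, t, 0.025, "step_right", 1000)
    spec = _spectral(x, t, 0.025, 1000)
    assert np.max(np.abs(img - spec)) < 1e-9


def test_analytic_solution_basics():
    x = np.linspace(-1, 1, 21)
    assert np.allclose(
        analytic_diffusion_solution(x, 3.0, 0.025, "uniform", 1000), 500.0
    )
    # mirror symmetry between the two step problems
    a = analytic_diffusion_solution(x, 0.7, 0.025, "step_left", 1000)
    b = analytic_diffusion_solution(-x, 0.7, 0.025, "step_right", 1000)
    assert np.array_equal(a, b)
    # t=0 returns the initial condition
    u0 = analytic_diffusion_solution(np.array([-0.5, 0.5]), 0.0, 0.025,
                                     "step_right", 1000)
    assert np.allclose(u0, [0.0, 1000.0])


def test_analytic_solution_equilibrates():
    # slowest zero-flux mode decays at D*pi^2/4; fully flat only at t >> 100
    x = np.linspace(-1, 1, 21)
    late = analytic_diffusion_solution(x, 500.0, 0.025, "step_right", 1000)
    assert np.max(np.abs(late - 500.0)) < 1e-8


def test_analytic_mass_is_conserved():
    x = np.arange(-1, 1 + 1e-12, 0.002)
    for t in (0.01, 0.4, 4.0):
        u = analytic_diffusion_solution(x, t, 0.025, "step_right", 1000)
        assert np.trapezoid(u, dx=0.002) == pytest.approx(1000.0, rel=1e-6)


# -- morphogen steady state -------------------------------------------------


def test_morphogen_steady_state_balances_production_and_decay():
    x = np.arange(-1, 1 + 1e-12, 0.001)
    us = hr.morphogen_steady_state(x, 0.05, 0.2, 125.0)
    assert np.trapezoid(us, dx=0.001) == pytest.approx(625.0, rel=1e-5)
    assert hr.morphogen_steady_state(np.array(-1.0), 0.05, 0.2, 0.0) == 0.0


def test_morphogen_steady_state_matches_banded_bvp_oracle():
    """Independent oracle: solve D u'' - mu u = 0 with the flux BCs as a
    banded linear system and compare at x = -1 to 4 significant figures."""
    D, mu, J = 0.05, 0.2, 125.0
    dx = 1e-3
    x = np.arange(-1, 1 + 1e-12, dx)
    n = len(x)
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    ab[1, :] = -2 * D / dx**2 - mu
    ab[0, 1:] = D / dx**2
    ab[2, :-1] = D / dx**2
    # ghost-node zero flux at x=-1, influx J at x=+1
    ab[0, 1] = 2 * D / dx**2
    ab[2, n - 2] = 2 * D / dx**2
    rhs[n - 1] = -2 * J / dx
    u = solve_banded((1, 1), ab, rhs)
    closed = hr.morphogen_steady_state(np.array(-1.0), D, mu, J)
    assert u[0] == pytest.approx(float(closed), rel=5e-4)
    assert float(closed) == pytest.approx(45.80, abs=0.01)


def test_morphogen_steady_state_is_pde_fixed_point():
    dxp = 0.01
    x = np.arange(0.0, 1.0 + 1e-12, dxp)  # the PDE region of the hybrid split
    us = hr.morphogen_steady_state(x, 0.05, 0.2, 125.0)
    op = _operator(
        PDEProblem(D=0.05, reaction="decay", mu=0.2, right_bc="influx",
                   J=125.0, left_bc="dirichlet"),
        len(x), dxp, 2.5e-5,
    )
    out = op.step(us, dirichlet_value=us[0])
    assert np.max(np.abs(out - us)) / us.max() < 1e-6


def test_pde_runner_uniform_stays_uniform():
    cfg = hr.diffusion_config("uniform", repeats=1, T_final=0.5, dt=1e-3)
    traj = hr.run_pde(cfg)
    assert np.allclose(traj.density[0, -1], 500.0, atol=1e-9)
    assert traj.mass[0, -1] == pytest.approx(1000.0, rel=1e-12)
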