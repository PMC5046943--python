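"""Binned densities, the normalised error, mass and speed estimators."""

import numpy as np
import pytest

import hybridrd as hr
from hybridrd.analysis import (
    bootstrap_variance_ci,
    moving_average,
    normalized_error,
    pde_bin_average,
)


@pytest.fixture()
def setup():
    cfg = hr.diffusion_config("uniform")
    part = hr.build_partition(cfg)
    return cfg, part


def test_binned_density_uniform(setup):
    cfg, part = setup
    state = hr.make_initial_condition(cfg, part)
    out = hr.binned_density(state, part)
    assert np.allclose(out, 500.0)
    state.A[:] = 0
    state.u[:] = 0.0
    assert np.all(hr.binned_density(state, part) == 0.0)


def test_pde_bin_average_exact_on_affine(setup):
    cfg, part = setup
    u = 2.0 + 3.0 * part.pde_nodes
    # first PDE bin [0, 0.05]: exact average 2 + 3*0.025 = 2.075
    assert pde_bin_average(u, part)[0] == pytest.approx(2.075, abs=1e-14)


def test_binned_density_overlap_average(setup):
    cfg, part = setup
    state = hr.make_initial_condition(cfg, part)
    state.u[:] = 400.0  # disagree with compartments (500) in the overlap
    comp = hr.binned_density(state, part, overlap="compartment")
    avg = hr.binned_density(state, part, overlap="average")
    n, C = part.overlap_index_start, part.n_compartments
    assert np.allclose(comp[n:C], 500.0)
    assert np.allclose(avg[n:C], 450.0)
    with pytest.raises(ValueError, match="overlap"):
        hr.binned_density(state, part, overlap="bogus")


def test_normalized_error_definition():
    a = np.zeros(10)
    b = np.zeros(10)
    assert normalized_error(a, b, N=100, h=0.1) == 0.0
    # one bin whose expected count differs by delta: E = delta / N
    b[3] = 5.0 / 0.1  # count difference 5 at h=0.1
    assert normalized_error(a, b, N=100, h=0.1) == pytest.approx(0.05)
    # invariant under bin relabelling
    perm = np.random.default_rng(0).permutation(10)
    assert normalized_error(a[perm], b[perm], 100, 0.1) == pytest.approx(0.05)
    with pytest.raises(ValueError, match="grid"):
        normalized_error(np.zeros(5), np.zeros(6), 1, 1.0)


def test_total_mass_counts_each_point_once(setup):
    cfg, part = setup
    state = hr.make_initial_condition(cfg, part)
    assert hr.total_mass(state, part) == pytest.approx(1000.0)
    # freezing the compartments, a zero-flux PDE step changes M only
    # through the Dirichlet node, bounded by the local flux per step
    op = hr.ThetaOperator(
        hr.PDEProblem(D=cfg.D, left_bc="dirichlet"), len(state.u), cfg.dxp, cfg.dt
    )
    u = state.u.copy()
    u_next = op.step(u, dirichlet_value=u[0])
    m_change = abs(
        np.trapezoid(u_next[part.l :], dx=cfg.dxp)
        - np.trapezoid(u[part.l :], dx=cfg.dxp)
    )
    slope = np.max(np.abs(np.gradient(u, cfg.dxp)))
    assert m_change <= cfg.D * slope * cfg.dt + 1e-9


def test_wave_speed_series_inverts_mass_growth():
    times = np.arange(0.0, 21.0, 1.0)
    k1, k2 = 1.0, 0.1
    const = np.full_like(times, 700.0)
    ws = hr.wave_speed_series(times, const, k1, k2)
    assert np.allclose(ws.speeds, 0.0)
    # M(t) = (k1/k2) * c * t with c = 2 -> speed = 2 everywhere
    mass = (k1 / k2) * 2.0 * times
    ws = hr.wave_speed_series(times, mass, k1, k2)
    assert np.allclose(ws.speeds, 2.0)
    assert np.allclose(ws.smoothed, 2.0)
    with pytest.raises(ValueError):
        hr.wave_speed_series(times[:1], const[:1], k1, k2)


def test_deterministic_fisher_speed_approaches_minimum():
    """Mean-field front speed tends to 2*sqrt(D*k1) = 2 from below."""
    cfg = hr.fisher_wave_config(repeats=1)
    traj = hr.run_pde(cfg, dt=1e-3)
    ws = hr.wave_speed_series(traj.times, traj.mass[0], cfg.k1, cfg.k2)
    late = ws.smoothed[(ws.times >= 10) & (ws.times <= 20)]
    assert np.all(late < 2.0)
    assert late[-1] == pytest.approx(2.0, rel=0.05)


def test_moving_average_windows():
    t = np.arange(10, dtype=float)
    assert np.allclose(moving_average(t, np.full(10, 3.0), 5.0), 3.0)
    alt = np.resize([1.0, -1.0], 10)
    out = moving_average(t, alt, 2.0)  # trailing window covers 2 points
    assert np.allclose(out[1:], 0.0)
    assert moving_average(np.array([4.0]), np.array([7.0]), 5.0)[0] == 7.0
    with pytest.raises(ValueError):
        moving_average(t, alt, 0.0)


def test_ensemble_stats_mean_and_unbiased_variance(small_uniform_run):
    summary = hr.ensemble_stats(small_uniform_run)
    assert summary.variance.min() >= 0.0
    assert summary.mean.shape == summary.variance.shape
    # hand-checkable case: two repeats differing by delta in one bin
    traj = small_uniform_run
    two = hr.Trajectory(
        times=traj.times[:1],
        x_centres=traj.x_centres,
        density=np.stack([traj.density[0, :1], traj.density[0, :1] + 4.0]),
        mass=traj.mass[:2, :1],
        regime=traj.regime,
        config=traj.config,
    )
    s = hr.ensemble_stats(two)
    assert np.allclose(s.variance, 16.0 / 2.0)  # delta^2/2 for n=2, ddof=1


def test_bootstrap_variance_ci_covers_sample_variance(rng):
    samples = rng.normal(0.0, 2.0, size=(120, 6))
    lo, hi = bootstrap_variance_ci(samples, n_boot=500, rng=rng)
    v = samples.var(axis=0, ddof=1)
    assert np.all(lo <= v) and np.all(v <= hi)
    assert np.all(lo >= 0.0)


def test_stochastic_equilibrium_variance_is_binomial():
    """Uniform equilibrium occupancy: per-bin count variance ~ N p(1-p)."""
    cfg = hr.diffusion_config(
        "uniform", N=200, repeats=60, T_final=1.0, dt=2.5e-5, seed=21
    )
    traj = hr.run_fully_stochastic(cfg)
    counts = traj.density[:, -1, :] * cfg.h
    var = counts.var(axis=0, ddof=1).mean()
    p = cfg.h / 2.0
    expected = cfg.N * p * (1 - p)
    assert var == pytest.approx(expected, rel=0.25)


def test_error_series_vanishes_for_exact_reference(small_uniform_run):
    E = hr.error_series(
        small_uniform_run, lambda x, t: np.full_like(x, 500.0)
    )
    assert E.iloc[0] == 0.0  # the initial condition is exact
    assert (E < 0.1).all()
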