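"""Interface flux / Dirichlet coupling operations and the coupled step."""

import numpy as np
import pytest

import hybridrd as hr
from hybridrd import _kernels
from hybridrd.coupling import _kernel_args
from hybridrd.pde import ThetaOperator


@pytest.fixture()
def diffusion_setup():
    cfg = hr.diffusion_config("uniform")
    part = hr.build_partition(cfg)
    return cfg, part


class _FixedRng:
    """Deterministic stand-in for a Generator (returns a fixed uniform)."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def test_interpolation_constant_and_affine(diffusion_setup):
    cfg, part = diffusion_setup
    u_const = np.full(len(part.pde_nodes), 7.0)
    assert hr.interpolate_pde_at_centre(u_const, part, 0.123) == 7.0
    u_affine = 2.0 + 3.0 * part.pde_nodes
    assert hr.interpolate_pde_at_centre(u_affine, part, 0.075) == pytest.approx(
        2.225, abs=1e-14
    )
    # bit-exact at a mesh node
    assert hr.interpolate_pde_at_centre(u_affine, part, part.pde_nodes[7]) == \
        u_affine[7]
    with pytest.raises(ValueError, match="outside"):
        hr.interpolate_pde_at_centre(u_affine, part, -0.5)


def test_transfer_probability_fick_identity(diffusion_setup):
    cfg, part = diffusion_setup
    for slope in (3.0, -3.0, 0.7):
        u = 2.0 + slope * part.pde_nodes
        flux = hr.interface_transfer_probability(u, part, cfg.D, 1e-3, cfg.h)
        expected = cfg.D * slope * 1e-3
        assert flux.psi == pytest.approx(expected, rel=1e-14)
    uniform = np.full(len(part.pde_nodes), 9.0)
    assert hr.interface_transfer_probability(uniform, part, cfg.D, 1e-3, cfg.h).psi == 0.0


def test_transfer_probability_rejects_multi_event_regime(diffusion_setup):
    cfg, part = diffusion_setup
    u = 2.0 + 3.0 * part.pde_nodes
    with pytest.raises(RuntimeError, match="psi"):
        hr.interface_transfer_probability(u, part, cfg.D, 1e4, cfg.h)


def test_apply_interface_transfer_rules():
    flux_in = hr.InterfaceFlux(0.3, 0.0, 0.0)
    A = np.array([4, 2])
    assert hr.apply_interface_transfer(A, flux_in, _FixedRng(0.2))[-1] == 3
    assert hr.apply_interface_transfer(A, flux_in, _FixedRng(0.5))[-1] == 2
    flux_out = hr.InterfaceFlux(-0.3, 0.0, 0.0)
    assert hr.apply_interface_transfer(A, flux_out, _FixedRng(0.1))[-1] == 1
    # removal from empty compartment: skipped and counted
    diags = {}
    out = hr.apply_interface_transfer(
        np.array([4, 0]), flux_out, _FixedRng(0.1), diags
    )
    assert out[-1] == 0 and diags["skipped_removals"] == 1
    # zero flux never changes the state
    assert np.array_equal(
        hr.apply_interface_transfer(A, hr.InterfaceFlux(0.0, 0, 0), _FixedRng(0.0)),
        A,
    )


def test_dirichlet_coupling_averages_straddling_compartments(diffusion_setup):
    cfg, part = diffusion_setup
    u = np.zeros(len(part.pde_nodes))
    A = np.zeros(part.n_compartments, dtype=int)
    n = part.overlap_index_start
    A[n - 1], A[n] = 10, 14
    out = hr.apply_dirichlet_coupling(u, A, part)
    assert out[0] == pytest.approx(240.0)  # (10+14)/(2*0.05)
    assert np.all(out[1:] == 0.0)
    # locally uniform count c -> density c/h, exactly
    A[n - 1] = A[n] = 25
    assert hr.apply_dirichlet_coupling(u, A, part)[0] == pytest.approx(500.0)
    # one-sided variant uses only the left compartment
    A[n - 1], A[n] = 10, 14
    assert hr.apply_dirichlet_coupling(u, A, part, one_sided=True)[0] == \
        pytest.approx(200.0)
    assert hr.apply_dirichlet_coupling(u, np.zeros_like(A), part)[0] == 0.0


def test_empty_system_stays_empty(diffusion_setup):
    cfg, part = diffusion_setup
    cfg = cfg.with_(N=0)
    state = hr.make_initial_condition(cfg, part)
    rng = np.random.default_rng(3)
    for _ in range(50):
        state = hr.hybrid_step(state, cfg, part, rng)
    assert np.all(state.A == 0) and np.all(state.u == 0.0)


def test_kernel_matches_reference_step_on_deterministic_path():
    """With an empty stochastic region and a flat PDE interior the coupled
    step is deterministic; the compiled chunk must track the numpy path."""
    cfg = hr.diffusion_config("step_right", repeats=1)
    part = hr.build_partition(cfg)
    state_py = hr.make_initial_condition(cfg, part)
    state_py.A[:] = 0  # no stochastic events, psi = 0 on the plateau
    state_k = state_py.copy()
    op = ThetaOperator(
        hr.coupling.pde_problem_for(cfg), len(part.pde_nodes), cfg.dxp, cfg.dt
    )
    rng = np.random.default_rng(0)
    for _ in range(50):
        state_py = hr.hybrid_step(state_py, cfg, part, rng, operator=op)
    kargs = _kernel_args(cfg, part, op)
    diag = np.zeros(6)
    _kernels.seed_rng(0)
    _kernels.hybrid_chunk(state_k.A, state_k.u, 50, diag=diag, **kargs)
    assert np.allclose(state_k.u, state_py.u, rtol=1e-9, atol=1e-9)
    assert np.array_equal(state_k.A, state_py.A)


def test_run_hybrid_is_deterministic_given_seed():
    cfg = hr.diffusion_config("uniform", repeats=2, T_final=0.3, seed=77)
    a = hr.run_hybrid(cfg)
    b = hr.run_hybrid(cfg)
    assert np.array_equal(a.density, b.density)
    assert np.array_equal(a.mass, b.mass)


def test_expected_mass_conserved_and_overlap_consistent(small_uniform_run):
    traj = small_uniform_run
    R = traj.repeats
    # ensemble-mean total mass stays within 3 SE of N at the final time
    se = traj.mass[:, -1].std(ddof=1) / np.sqrt(R)
    assert abs(traj.mass[:, -1].mean() - 1000.0) <= 3 * se
    # overlap bins: ensemble-mean compartment density tracks N/|Omega|
    part = hr.build_partition(traj.config)
    ov = slice(part.overlap_index_start, part.n_compartments)
    mean = traj.density[:, -1, ov].mean(axis=0)
    se_ov = traj.density[:, -1, ov].std(axis=0, ddof=1) / np.sqrt(R)
    assert np.all(np.abs(mean - 500.0) <= 3 * se_ov)


def test_interface_skip_rate_is_reported(small_uniform_run):
    assert "skipped_removals" in small_uniform_run.diagnostics
    assert small_uniform_run.diagnostics["max_abs_psi"] < 1.0
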