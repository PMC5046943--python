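"""Shared fixtures.

The session-scoped fixtures below hold the full-size ensemble runs of
the three canonical study problems; several acceptance-level tests
reuse each run (mean profiles, error series, variances), so they are
computed once per session.  Seeds are fixed arbitrary constants chosen
up front so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import hybridrd as hr


@pytest.fixture(scope="session")
def eq_trajectory():
    """Uniform-IC diffusion, hybrid, 100 repeats to t=10."""
    return hr.run_hybrid(hr.diffusion_config("uniform", seed=101))


@pytest.fixture(scope="session")
def step_right_trajectory():
    """Step IC with all mass in [0,1] (PDE side), hybrid, 100 repeats."""
    return hr.run_hybrid(hr.diffusion_config("step_right", seed=202))


@pytest.fixture(scope="session")
def step_left_trajectory():
    """Step IC with all mass in [-1,0] (stochastic side), hybrid, 100 repeats."""
    return hr.run_hybrid(hr.diffusion_config("step_left", seed=303))


@pytest.fixture(scope="session")
def stoch_step_right_trajectory():
    """Fully stochastic reference for the step_right problem."""
    return hr.run_fully_stochastic(
        hr.diffusion_config("step_right", seed=404, dt=5e-6)
    )


@pytest.fixture(scope="session")
def morphogen_trajectory():
    """Morphogen gradient, hybrid, 100 repeats to t=20."""
    return hr.run_hybrid(hr.morphogen_config(seed=505))


@pytest.fixture(scope="session")
def stoch_morphogen_trajectory():
    return hr.run_fully_stochastic(hr.morphogen_config(stochastic=True, seed=606))


@pytest.fixture(scope="session")
def wave_hybrid_trajectory():
    """Fixed-interface travelling wave, hybrid, 200 repeats to t=20."""
    return hr.run_hybrid(hr.fisher_wave_config(seed=707))


@pytest.fixture(scope="session")
def wave_stochastic_trajectory():
    return hr.run_fully_stochastic(hr.fisher_wave_config(seed=808))


@pytest.fixture(scope="session")
def wave_pde_trajectory():
    """Deterministic (mean-field) travelling wave oracle."""
    return hr.run_pde(hr.fisher_wave_config(), dt=1e-3)


@pytest.fixture(scope="session")
def wave_adaptive_trajectory():
    return hr.run_hybrid(hr.fisher_wave_config(adaptive=True, seed=909))


@pytest.fixture(scope="session")
def small_uniform_run():
    """A light uniform-IC hybrid run for unit-level checks."""
    return hr.run_hybrid(
        hr.diffusion_config("uniform", repeats=30, T_final=1.0, seed=1111)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fraction_within(z: np.ndarray) -> float:
    """Fraction of |z| scores within 3 (per-bin agreement with a 3-sigma
    band; a handful of ~40+ bins is expected to exceed it by chance)."""
    return float(np.mean(np.abs(z) <= 3.0))
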