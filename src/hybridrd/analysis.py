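"""Metrics and estimators for simulation output.

Everything here works on the width-``h`` output grid that tiles the
full domain: compartment bins report ``A/h``, PDE bins report the
trapezoidal bin average of the nodal density, and overlap bins report
either the compartment value (fixed-interface default) or the mean of
the two descriptions.

The normalised error E compares an ensemble-mean binned density with a
reference profile evaluated at the bin centres:

    E = (h / N) * sum_bins |mean - reference|
      = (1 / N)  * sum_bins |expected-count difference|,

i.e. the total absolute count discrepancy as a fraction of the N
particles in the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainPartition, HybridState, Trajectory, _require_integer

__all__ = [
    "EnsembleSummary",
    "WaveSpeedSeries",
    "binned_density",
    "pde_bin_average",
    "normalized_error",
    "total_mass",
    "wave_speed_series",
    "moving_average",
    "ensemble_stats",
    "bootstrap_variance_ci",
]


def pde_bin_average(u: np.ndarray, partition: DomainPartition) -> np.ndarray:
    """Trapezoidal average of the PDE density over each width-h bin of
    the PDE region [I0, domain_hi] (exact for affine fields)."""
    w = partition.w
    n_bins = (len(u) - 1) // w
    weights = np.ones(w + 1)
    weights[0] = weights[-1] = 0.5
    out = np.empty(n_bins)
    for j in range(n_bins):
        out[j] = np.dot(u[j * w : j * w + w + 1], weights) / w
    return out


def binned_density(
    state: HybridState,
    partition: DomainPartition,
    overlap: str = "compartment",
) -> np.ndarray:
    """Particle density on the width-h grid over the full domain.

    ``overlap`` chooses the overlap-bin convention: ``compartment``
    (default) or ``average`` (mean of compartment and PDE values).
    """
    h = partition.h
    C = partition.n_compartments
    n = partition.overlap_index_start
    B = _require_integer(
        (partition.domain_hi - partition.domain_lo) / h, "(domain_hi-domain_lo)/h"
    )
    out = np.empty(B)
    out[:C] = state.A / h
    pde_bins = pde_bin_average(state.u, partition)  # bins n .. B-1
    out[C:] = pde_bins[C - n :]
    if overlap == "average":
        out[n:C] = 0.5 * (out[n:C] + pde_bins[: C - n])
    elif overlap != "compartment":
        raise ValueError(f"unknown overlap convention {overlap!r}")
    return out


def total_mass(state: HybridState, partition: DomainPartition) -> float:
    """Total particle mass; compartments own [domain_lo, I1], the PDE
    region (I1, domain_hi] is integrated with the trapezoidal rule."""
    pde_part = float(np.trapezoid(state.u[partition.l :],
                                  dx=partition.dxp))
    return float(state.A.sum()) + pde_part


def normalized_error(
    mean_density: np.ndarray,
    reference_density: np.ndarray,
    N: float,
    h: float,
) -> float:
    """Total absolute expected-count discrepancy per particle (see module
    docstring).  Both fields must live on the same width-h grid."""
    mean_density = np.asarray(mean_density, dtype=float)
    reference_density = np.asarray(reference_density, dtype=float)
    if mean_density.shape != reference_density.shape:
        raise ValueError(
            f"grid mismatch: {mean_density.shape} vs {reference_density.shape}"
        )
    return float(h * np.abs(mean_density - reference_density).sum() / N)


@dataclass
class WaveSpeedSeries:
    """Front-speed estimates derived from the total-mass record M(t).

    A travelling front of height k1/k2 advancing at speed c grows the
    total mass at rate c*k1/k2, so speed = (k2/k1) * dM/dt.
    """

    times: np.ndarray            # mid-points of the differencing intervals
    mass: np.ndarray             # M at the sampled times
    mass_times: np.ndarray
    speeds: np.ndarray
    smoothed: np.ndarray
    window: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "speed": self.speeds, "smoothed": self.smoothed}
        )


def wave_speed_series(
    times: np.ndarray,
    mass: np.ndarray,
    k1: float,
    k2: float,
    stride: int = 1,
    window: float = 5.0,
) -> WaveSpeedSeries:
    """Speed estimates (k2/k1)·ΔM/Δt over consecutive stride-separated
    sample pairs, smoothed with a trailing moving average."""
    times = np.asarray(times, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if len(times) < stride + 1:
        raise ValueError("need at least stride+1 mass samples")
    t0, t1 = times[:-stride:stride], times[stride::stride]
    m0, m1 = mass[:-stride:stride], mass[stride::stride]
    speeds = (k2 / k1) * (m1 - m0) / (t1 - t0)
    mid = 0.5 * (t0 + t1)
    smoothed = moving_average(mid, speeds, window)
    return WaveSpeedSeries(mid, mass, times, speeds, smoothed, window)


def moving_average(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Trailing moving average: each output is the mean of all values
    whose times fall in (t - window, t]."""
    if window <= 0:
        raise ValueError("window must be > 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i, t in enumerate(times):
        sel = (times > t - window) & (times <= t)
        out[i] = values[sel].mean()
    return out


@dataclass
class EnsembleSummary:
    """Per-bin sample mean and unbiased variance across repeats."""

    x_centres: np.ndarray
    times: np.ndarray
    mean: np.ndarray      # (times, bins)
    variance: np.ndarray  # (times, bins)
    repeats: int

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        s = int(np.argmin(np.abs(self.times - t)))
        return self.mean[s], self.variance[s]


def ensemble_stats(trajectory: Trajectory) -> EnsembleSummary:
    """Mean and unbiased variance of the binned density across repeats."""
    if trajectory.repeats < 2:
        raise ValueError("need at least 2 repeats for ensemble statistics")
    return EnsembleSummary(
        x_centres=trajectory.x_centres,
        times=trajectory.times,
        mean=trajectory.density.mean(axis=0),
        variance=trajectory.density.var(axis=0, ddof=1),
        repeats=trajectory.repeats,
    )


def error_series(trajectory: Trajectory, reference) -> pd.Series:
    """Normalised error E(t) of the ensemble-mean binned density against
    ``reference(x, t)`` (a density field, evaluated at bin centres)."""
    cfg = trajectory.config
    mean = trajectory.mean_density()
    E = [
        normalized_error(
            mean[s], reference(trajectory.x_centres, t), cfg.N, cfg.h
        )
        for s, t in enumerate(trajectory.times)
    ]
    return pd.Series(E, index=trajectory.times, name="E")


def noise_floor_series(trajectory: Trajectory) -> pd.Series:
    """Expected value of E under the zero-bias hypothesis.

    With unbiased per-bin means, |mean - reference| has expectation
    SE_b * sqrt(2/pi) (half-normal), so the Monte-Carlo floor of the
    normalised error is (h/N) * sqrt(2/pi) * sum_b SE_b(t).  Comparing
    E(t) against this floor separates genuine coupling bias from the
    ensemble noise, whose magnitude changes over time as mass moves
    between the regimes."""
    cfg = trajectory.config
    R = trajectory.repeats
    se = trajectory.density.std(axis=0, ddof=1) / np.sqrt(R)  # (S, B)
    floor = (cfg.h / cfg.N) * np.sqrt(2.0 / np.pi) * se.sum(axis=1)
    return pd.Series(floor, index=trajectory.times, name="E_floor")


def bootstrap_error_se(
    trajectory: Trajectory,
    reference,
    t: float,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap (over repeats) standard error of E at time ``t``."""
    rng = rng or np.random.default_rng(0)
    cfg = trajectory.config
    s = int(np.argmin(np.abs(trajectory.times - t)))
    ref = reference(trajectory.x_centres, trajectory.times[s])
    dens = trajectory.density[:, s, :]
    R = dens.shape[0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, R, R)
        vals[b] = normalized_error(dens[idx].mean(axis=0), ref, cfg.N, cfg.h)
    return float(vals.std(ddof=1))


def scan_error(
    param: str,
    values,
    t_eval: float = 1.0,
    repeats: int = 100,
    seed: int = 0,
    **overrides,
) -> pd.DataFrame:
    """Sensitivity of the normalised error to an algorithm parameter.

    Runs the step-initial-condition diffusion problem for each value of
    ``param`` in {'h', 'dxp', 'm'} and evaluates E at ``t_eval`` against
    the image-series analytic solution, with a bootstrap standard error.
    """
    from .configs import sensitivity_config
    from .coupling import run_hybrid
    from .pde import analytic_diffusion_solution

    if param not in ("h", "dxp", "m"):
        raise ValueError(f"param must be 'h', 'dxp' or 'm', not {param!r}")
    rows = []
    for v in values:
        cfg = sensitivity_config(
            repeats=repeats, seed=seed, T_final=t_eval, **{param: v}, **overrides
        )
        traj = run_hybrid(cfg)

        def ref(x, t):
            return analytic_diffusion_solution(x, t, cfg.D, cfg.ic_name, cfg.N)

        E = error_series(traj, ref).iloc[-1]
        se = bootstrap_error_se(traj, ref, t_eval)
        rows.append({"param": param, "value": v, "E": float(E), "se": se})
    return pd.DataFrame(rows)


def bootstrap_variance_ci(
    samples: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for the per-bin unbiased variance of
    ``samples`` (repeats x bins)."""
    rng = rng or np.random.default_rng(0)
    samples = np.asarray(samples, dtype=float)
    R = samples.shape[0]
    idx = rng.integers(0, R, size=(n_boot, R))
    boots = samples[idx].var(axis=1, ddof=1)  # (n_boot, bins)
    q = (1.0 - level) / 2.0
    return np.quantile(boots, q, axis=0), np.quantile(boots, 1.0 - q, axis=0)
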