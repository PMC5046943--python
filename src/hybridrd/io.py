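"""Configuration parsing and trajectory/summary writers.

Config files are flat YAML (JSON is a YAML subset) mapping
:class:`~hybridrd.core.SimulationConfig` field names to values; a
commented template ships with the package (``config_template.yaml``).
Trajectories are written as long-form CSV (repeat, time, x_centre,
density, regime) with a JSON sidecar manifest carrying the full
config, seed and run diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SimulationConfig, Trajectory

__all__ = ["parse_config", "config_to_dict", "write_trajectory", "read_trajectory"]

#: keys that must be present in a config document (everything else defaults)
REQUIRED_KEYS = (
    "domain_lo",
    "domain_hi",
    "D",
    "dt",
    "h",
    "dxp",
    "I0",
    "I1",
    "T_final",
    "N",
)

_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def parse_config(source) -> SimulationConfig:
    """Build a validated config from a mapping or a YAML/JSON file path.

    Raises with the offending field name on unknown keys, missing
    required keys, or any violated invariant (via config validation).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"config file {source} does not contain a mapping")
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        raise TypeError(f"cannot parse a config from {type(source).__name__}")
    unknown = set(doc) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in REQUIRED_KEYS if k not in doc]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    return SimulationConfig(**doc)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def _version() -> str:
    try:
        return metadata.version("hybridrd")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_trajectory(trajectory: Trajectory, path) -> Path:
    """Write the long-form CSV plus a ``.manifest.json`` sidecar.

    Densities are written with 17 significant digits so that reading
    the file back reproduces them bit-exactly.
    """
    path = Path(path)
    R, S, B = trajectory.density.shape
    rep, s, b = np.meshgrid(
        np.arange(R), np.arange(S), np.arange(B), indexing="ij"
    )
    frame = pd.DataFrame(
        {
            "repeat": rep.ravel(),
            "time": trajectory.times[s.ravel()],
            "x_centre": trajectory.x_centres[b.ravel()],
            "density": trajectory.density.ravel(),
            "regime": trajectory.regime[b.ravel()],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    manifest = {
        "config": config_to_dict(trajectory.config),
        "seed": trajectory.config.seed,
        "mode": trajectory.mode,
        "diagnostics": trajectory.diagnostics,
        "times": [float(t) for t in trajectory.times],
        "mass": np.asarray(trajectory.mass).tolist(),
        "version": _version(),
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return path


def read_trajectory(path) -> Trajectory:
    """Reconstruct a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text()
    )
    frame = pd.read_csv(path, float_precision="round_trip")
    config = SimulationConfig(**manifest["config"])
    times = np.array(manifest["times"])
    x = np.sort(frame["x_centre"].unique())
    R = frame["repeat"].nunique()
    density = (
        frame.sort_values(["repeat", "time", "x_centre"])["density"]
        .to_numpy()
        .reshape(R, len(times), len(x))
    )
    regime = (
        frame.drop_duplicates("x_centre").sort_values("x_centre")["regime"].to_numpy()
    )
    return Trajectory(
        times=times,
        x_centres=x,
        density=density,
        mass=np.array(manifest["mass"]),
        regime=regime,
        config=config,
        mode=manifest["mode"],
        diagnostics=manifest["diagnostics"],
    )
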