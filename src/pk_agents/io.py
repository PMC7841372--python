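"""Config, trajectory, and sweep-result readers/writers.

JSON for configs and run manifests, tidy CSV for trajectories and sweep
tables.  Floats are serialized with 17 significant digits so a written
file round-trips to the exact binary values.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .dynamics import Trajectory
from .experiments import RESULT_COLUMNS, SweepResult

__all__ = [
    "load_config", "save_config", "write_trajectory", "read_trajectory_table",
    "write_results", "read_results", "RunManifest", "write_manifest",
]

_FLOAT_FMT = "%.17g"


def load_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a JSON file.

    Missing keys take the model defaults (L=5, kappa=0.05, xi=0.5, r=1,
    n_steps=2500, ...); unknown keys warn and are ignored; invariant
    violations raise with the offending field named.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a JSON object")
    known = SimulationConfig.field_names()
    unknown = sorted(set(data) - known)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(unknown)}",
                      stacklevel=2)
    return SimulationConfig(**{k: v for k, v in data.items() if k in known})


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def trajectory_table(traj: Trajectory) -> pd.DataFrame:
    """Long-form table: one row per agent per step (step, agent_id, x, y, theta)."""
    T1, n = traj.headings.shape
    return pd.DataFrame({
        "step": np.repeat(np.arange(T1), n),
        "agent_id": np.tile(np.arange(n), T1),
        "x": traj.positions[..., 0].ravel(),
        "y": traj.positions[..., 1].ravel(),
        "theta": traj.headings.ravel(),
    })


def write_trajectory(traj: Trajectory, path) -> None:
    trajectory_table(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_results(result: SweepResult, path) -> None:
    """Write a sweep table as tidy CSV (deterministic row order)."""
    result.table[RESULT_COLUMNS].to_csv(path, index=False,
                                        float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class RunManifest:
    """Everything needed to regenerate an output exactly: the resolved
    config, master seed, code version, and output paths."""

    config: dict
    master_seed: int
    outputs: list = field(default_factory=list)
    command: str = ""
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
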