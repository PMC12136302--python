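"""Trajectory serialization.

HDF5 layout (version 1):

    /times                  (T,)   float64, recorded instants
    /ve, /vi, /k            (T, N) float64, one row per recorded instant
    attrs: layout_version = 1, config = resolved YAML config string

The embedded config string is the full resolved run configuration, so any
trajectory file can be regenerated bit-identically from itself.  A long-
format CSV exporter (time, node, x, ve, vi, k) is provided for
interoperability.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .analysis import space_time_matrix
from .config import RunConfig
from .integrate import IntegrationSettings, Trajectory
from .field import FieldState

__all__ = ["FormatError", "write_trajectory", "read_trajectory", "trajectory_to_csv"]

_LAYOUT_VERSION = 1


class FormatError(RuntimeError):
    """Trajectory file is corrupt or has an unexpected layout."""


def write_trajectory(traj: Trajectory, path: str | Path, cfg: RunConfig) -> None:
    """Write a trajectory (with its resolved config) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = _LAYOUT_VERSION
        f.attrs["config"] = cfg.to_yaml()
        f.attrs["config_hash"] = cfg.config_hash()
        f.create_dataset("times", data=traj.times)
        for name in ("ve", "vi", "k"):
            f.create_dataset(name, data=space_time_matrix(traj, name))


def read_trajectory(path: str | Path) -> tuple[Trajectory, RunConfig]:
    """Read a trajectory back; lossless for times and all three fields."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("layout_version") != _LAYOUT_VERSION:
                raise FormatError(
                    f"{path}: unsupported or missing layout_version "
                    f"(expected {_LAYOUT_VERSION})"
                )
            missing = {"times", "ve", "vi", "k"} - set(f.keys())
            if missing:
                raise FormatError(f"{path}: missing datasets {sorted(missing)}")
            times = f["times"][()]
            ve = f["ve"][()]
            vi = f["vi"][()]
            k = f["k"][()]
            cfg = RunConfig.from_dict(
                __import__("yaml").safe_load(f.attrs["config"])
            )
    except OSError as e:
        raise FormatError(f"{path}: not a readable HDF5 file ({e})") from e
    if not (ve.shape == vi.shape == k.shape and ve.shape[0] == len(times)):
        raise FormatError(f"{path}: inconsistent dataset shapes")
    grid = cfg.grid()
    if ve.shape[1] != grid.n_nodes:
        raise FormatError(
            f"{path}: field width {ve.shape[1]} does not match grid "
            f"n_nodes {grid.n_nodes} of the embedded config"
        )
    states = [FieldState(ve[i], vi[i], k[i]) for i in range(len(times))]
    traj = Trajectory(
        times=times,
        states=states,
        grid=grid,
        params=cfg.model_parameters(),
        settings=cfg.integration_settings(),
    )
    return traj, cfg


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Long-format CSV export: one row per (time, node)."""
    import pandas as pd

    T = len(traj)
    n = traj.grid.n_nodes
    df = pd.DataFrame(
        {
            "time": np.repeat(traj.times, n),
            "node": np.tile(np.arange(n), T),
            "x": np.tile(traj.grid.coords, T),
            "ve": space_time_matrix(traj, "ve").ravel(),
            "vi": space_time_matrix(traj, "vi").ravel(),
            "k": space_time_matrix(traj, "k").ravel(),
        }
    )
    df.to_csv(path, index=False)
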