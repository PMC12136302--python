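"""Figure export: space-time heatmaps, sweep curves, bifurcation diagrams."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import BifurcationDiagram, RegimeLabel, space_time_matrix
from .experiments import SweepResult
from .integrate import Trajectory

__all__ = ["plot_space_time", "plot_sweep", "plot_bifurcation"]


def plot_space_time(traj: Trajectory, path: str | Path) -> None:
    """Three-panel heatmap (ve, vi, k) over space and time."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), constrained_layout=True)
    titles = {"ve": "excitatory potential", "vi": "inhibitory potential", "k": "extracellular K+"}
    extent = [traj.grid.coords[0], traj.grid.coords[-1], traj.times[-1], traj.times[0]]
    for ax, field in zip(axes, ("ve", "vi", "k")):
        m = space_time_matrix(traj, field)
        im = ax.imshow(m, aspect="auto", extent=extent, cmap="viridis")
        ax.set_title(titles[field])
        ax.set_xlabel("x (grid units)")
        fig.colorbar(im, ax=ax)
    axes[0].set_ylabel("time (model units)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(result: SweepResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    speeds = result.speeds_mm_per_min()
    ax.plot(result.values, speeds, "o-")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel("propagation speed (mm/min)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bifurcation(diagram: BifurcationDiagram, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5), constrained_layout=True)
    ax.plot(diagram.kv_star_values, diagram.max_ve, "o", color="tab:blue", label="max ve")
    ax.plot(diagram.kv_star_values, diagram.min_ve, "o", color="tab:red", label="min ve")
    if diagram.transition is not None:
        ax.axvline(diagram.transition, color="k", ls="--", lw=1, label="transition")
    prop = np.array([lb is RegimeLabel.PROPAGATING for lb in diagram.labels])
    ax.plot(diagram.kv_star_values[prop], diagram.max_ve[prop], "o", mfc="none", mec="k", ms=10)
    ax.set_xlabel("kv*")
    ax.set_ylabel("ve extrema at probe node")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
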