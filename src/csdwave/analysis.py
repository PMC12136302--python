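"""Trajectory analysis: wavefront detection, propagation speed, regime
classification, per-node extrema and space-time matrices.

The headline speed estimator divides the final rightward wavefront
displacement by the full horizon:

    nu = hx * (nth - N//2) / tF

where nth is the outermost node (right of center) whose excitatory
potential exceeds the wavefront threshold in the final snapshot.  Because
it uses only the final front position, this estimator folds the initiation
latency into the average; a secondary front-tracking estimate (least-squares
slope of the front position over the second half of the run) is reported
alongside for diagnostics.  Headline numbers always use the final-front
formula.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .field import Grid
from .integrate import Trajectory

__all__ = [
    "UnitCalibration",
    "SpeedMeasurement",
    "RegimeLabel",
    "BifurcationDiagram",
    "MeasurementError",
    "detect_wavefront",
    "front_positions",
    "propagation_speed",
    "node_extrema",
    "classify_regime",
    "space_time_matrix",
]


class MeasurementError(RuntimeError):
    """No suprathreshold wavefront at the measurement time."""


@dataclass(frozen=True)
class UnitCalibration:
    """Bridge from model units to physical units.

    mm_per_grid_unit: physical length of one grid coordinate unit.
    seconds_per_time_unit: physical duration of one model time unit.
    Speeds convert as mm/min = model_speed * mm_per_grid_unit /
    seconds_per_time_unit * 60.
    """

    mm_per_grid_unit: float
    seconds_per_time_unit: float = 1.0

    def __post_init__(self) -> None:
        if not self.mm_per_grid_unit > 0:
            raise ValueError("mm_per_grid_unit must be > 0")
        if not self.seconds_per_time_unit > 0:
            raise ValueError("seconds_per_time_unit must be > 0")

    def to_mm_per_min(self, speed_model_units: float) -> float:
        return speed_model_units * self.mm_per_grid_unit / self.seconds_per_time_unit * 60.0


@dataclass(frozen=True)
class SpeedMeasurement:
    """Result of the final-front velocity estimate."""

    nth: int
    threshold: float
    t_final: float
    speed_model_units: float
    speed_mm_per_min: float
    front_tracking_model_units: float | None = None


class RegimeLabel(str, enum.Enum):
    QUIESCENT = "quiescent"
    PROPAGATING = "propagating"


@dataclass
class BifurcationDiagram:
    """Scan of the potassium-drive threshold kv* versus dynamical regime."""

    kv_star_values: np.ndarray
    max_ve: np.ndarray
    min_ve: np.ndarray
    labels: list[RegimeLabel]
    transition: float | None
    multistability_warning: bool = False

    def __post_init__(self) -> None:
        self.kv_star_values = np.asarray(self.kv_star_values, dtype=float)
        if not np.all(np.diff(self.kv_star_values) > 0):
            raise ValueError("kv_star_values must be strictly increasing")


def detect_wavefront(ve_snapshot: np.ndarray, threshold: float, grid: Grid) -> int | None:
    """Outermost suprathreshold node right of center, or None.

    Returns the largest index j >= N//2 with ve_j >= threshold.  By the
    mirror symmetry of a centered stimulus the leftward front is redundant.
    """
    ve = np.asarray(ve_snapshot, dtype=float)
    if len(ve) != grid.n_nodes:
        raise ValueError(
            f"snapshot length {len(ve)} does not match grid n_nodes {grid.n_nodes}"
        )
    c = grid.center_index
    above = np.nonzero(ve[c:] >= threshold)[0]
    if len(above) == 0:
        return None
    return int(c + above[-1])


def front_positions(traj: Trajectory, threshold: float) -> np.ndarray:
    """Front index per recorded snapshot (NaN where no front)."""
    out = np.full(len(traj), np.nan)
    for i, st in enumerate(traj.states):
        j = detect_wavefront(st.ve, threshold, traj.grid)
        if j is not None:
            out[i] = j
    return out


def _front_tracking_slope(traj: Trajectory, threshold: float) -> float | None:
    """Least-squares slope (grid units / time) of the front position over
    the second half of the run; None when too few front points exist."""
    fr = front_positions(traj, threshold)
    half = len(traj) // 2
    t = traj.times[half:]
    f = fr[half:]
    ok = ~np.isnan(f)
    if ok.sum() < 3:
        return None
    slope_nodes = np.polyfit(t[ok], f[ok], 1)[0]
    return float(slope_nodes * traj.grid.spacing)


def propagation_speed(
    traj: Trajectory, threshold: float, cal: UnitCalibration
) -> SpeedMeasurement:
    """Final-front propagation velocity, converted to mm/min.

    Raises :class:`MeasurementError` when no suprathreshold front exists in
    the final snapshot (the wave did not form or died).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    nth = detect_wavefront(traj.states[-1].ve, threshold, traj.grid)
    if nth is None:
        raise MeasurementError(
            f"no wavefront above threshold {threshold} at t={traj.times[-1]:.6g}"
        )
    t_final = float(traj.times[-1])
    v = traj.grid.spacing * (nth - traj.grid.center_index) / t_final
    return SpeedMeasurement(
        nth=nth,
        threshold=threshold,
        t_final=t_final,
        speed_model_units=v,
        speed_mm_per_min=cal.to_mm_per_min(v),
        front_tracking_model_units=_front_tracking_slope(traj, threshold),
    )


def node_extrema(
    traj: Trajectory, node: int, discard_fraction: float = 0.0
) -> tuple[float, float]:
    """(max, min) of the excitatory potential at one node after discarding
    the initial ``discard_fraction`` of the horizon (transient removal)."""
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    if not 0 <= node < traj.grid.n_nodes:
        raise ValueError(f"node {node} out of range")
    t0 = discard_fraction * traj.times[-1]
    vals = [st.ve[node] for t, st in zip(traj.times, traj.states) if t >= t0]
    if not vals:
        raise ValueError("no snapshots remain after transient discard")
    return float(np.max(vals)), float(np.min(vals))


def classify_regime(
    traj: Trajectory, threshold: float, reach_fraction: float
) -> RegimeLabel:
    """Propagating iff the final front covered at least ``reach_fraction``
    of the half-axis: (nth - N//2) >= reach_fraction * (N//2)."""
    if not 0.0 < reach_fraction <= 1.0:
        raise ValueError("reach_fraction must lie in (0, 1]")
    nth = detect_wavefront(traj.states[-1].ve, threshold, traj.grid)
    c = traj.grid.center_index
    if nth is not None and (nth - c) >= reach_fraction * c:
        return RegimeLabel.PROPAGATING
    return RegimeLabel.QUIESCENT


_FIELDS = ("ve", "vi", "k")


def space_time_matrix(traj: Trajectory, field: str) -> np.ndarray:
    """Dense time x node matrix of one field (rows = recorded times)."""
    if field not in _FIELDS:
        raise ValueError(f"unknown field {field!r}; expected one of {_FIELDS}")
    return np.stack([getattr(st, field) for st in traj.states])
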