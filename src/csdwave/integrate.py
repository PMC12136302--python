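"""Time integration of the discretized field (method of lines).

Fixed-step classical Runge-Kutta (RK4).  A fixed step was chosen over an
adaptive one because the firing-rate transfer function is discontinuous in
the potassium variable, which makes embedded error estimators unreliable;
convergence is instead established by the dt-halving and grid-refinement
tests.  The integrator refuses steps above 90% of the explicit diffusion
stability bound and aborts with a diagnostic when the state leaves the
finite range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import FieldState, Grid, ModelParameters, interaction_matrix, rhs

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "StabilityError",
    "DivergenceError",
    "initial_state",
    "max_stable_dt",
    "simulate",
]


class StabilityError(ValueError):
    """Requested time step violates the explicit diffusion stability bound."""


class DivergenceError(RuntimeError):
    """State became non-finite during integration."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Step size, horizon, snapshot decimation and (reserved) seed.

    The model is deterministic; ``seed`` is carried for forward
    compatibility and provenance but never consumed.
    """

    dt: float
    t_final: float
    record_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.t_final >= self.dt:
            raise ValueError(
                f"t_final must be >= dt, got t_final={self.t_final}, dt={self.dt}"
            )
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")


@dataclass
class Trajectory:
    """Recorded simulation output: times, states, grid and parameters."""

    times: np.ndarray
    states: list[FieldState]
    grid: Grid
    params: ModelParameters
    settings: IntegrationSettings

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def initial_state(grid: Grid, v0: float, k0: float, params: ModelParameters | None = None) -> FieldState:
    """Uniform initial state ve = vi = v0, k = k0.

    When ``params`` is given, the resting potassium level is checked to lie
    below the hyperactivity regime (k0 < k1* of both populations) and must
    be non-negative.
    """
    if k0 < 0:
        raise ValueError(f"k0 must be >= 0, got {k0}")
    if params is not None:
        k1_min = min(params.transfer_e.k1_star, params.transfer_i.k1_star)
        if not k0 < k1_min:
            raise ValueError(
                f"resting potassium k0={k0} must lie below the lower "
                f"threshold k1*={k1_min} of both populations"
            )
    n = grid.n_nodes
    return FieldState(np.full(n, float(v0)), np.full(n, float(v0)), np.full(n, float(k0)))


def max_stable_dt(grid: Grid, delta: float, tau: float) -> float:
    """Explicit-scheme diffusion step bound tau hx^2 / (2 delta).

    Infinite when delta = 0 (no diffusion, no bound from this term).
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if delta == 0:
        return np.inf
    return tau * grid.spacing**2 / (2.0 * delta)


def simulate(
    params: ModelParameters,
    grid: Grid,
    init: FieldState,
    settings: IntegrationSettings,
) -> Trajectory:
    """Advance the field with fixed-step RK4 and record snapshots.

    Records the initial state, every ``record_every``-th step and the final
    step.  Identical inputs give bit-identical trajectories.

    Raises
    ------
    StabilityError
        If dt exceeds 0.9x the diffusion stability bound.
    DivergenceError
        If the state becomes non-finite, naming the first bad time.
    """
    bound = max_stable_dt(grid, params.coupling.delta, params.coupling.tau)
    if settings.dt > 0.9 * bound:
        raise StabilityError(
            f"dt={settings.dt} exceeds 0.9 x stability bound "
            f"({0.9 * bound:.6g}); reduce dt or diffusion"
        )
    if len(init.ve) != grid.n_nodes:
        raise ValueError("initial state does not match grid size")

    W = interaction_matrix(grid)
    dt = settings.dt
    n_steps = int(round(settings.t_final / dt))

    ve = init.ve.astype(float).copy()
    vi = init.vi.astype(float).copy()
    k = init.k.astype(float).copy()

    times = [0.0]
    states = [FieldState(ve.copy(), vi.copy(), k.copy())]

    def f(t, ve, vi, k):
        return rhs(FieldState(ve, vi, k), t, params, grid, W)

    t = 0.0
    for i in range(n_steps):
        try:
            a1 = f(t, ve, vi, k)
            a2 = f(t + dt / 2, ve + dt / 2 * a1[0], vi + dt / 2 * a1[1], k + dt / 2 * a1[2])
            a3 = f(t + dt / 2, ve + dt / 2 * a2[0], vi + dt / 2 * a2[1], k + dt / 2 * a2[2])
            a4 = f(t + dt, ve + dt * a3[0], vi + dt * a3[1], k + dt * a3[2])
        except ValueError as e:
            # a stage state left the finite range mid-step
            raise DivergenceError(
                f"state became non-finite at t={t + dt:.6g} ({e})"
            ) from e
        ve = ve + dt / 6 * (a1[0] + 2 * a2[0] + 2 * a3[0] + a4[0])
        vi = vi + dt / 6 * (a1[1] + 2 * a2[1] + 2 * a3[1] + a4[1])
        k = k + dt / 6 * (a1[2] + 2 * a2[2] + 2 * a3[2] + a4[2])
        t = (i + 1) * dt
        if not (np.isfinite(ve).all() and np.isfinite(vi).all() and np.isfinite(k).all()):
            raise DivergenceError(f"state became non-finite at t={t:.6g}")
        if (i + 1) % settings.record_every == 0 or i == n_steps - 1:
            times.append(t)
            states.append(FieldState(ve.copy(), vi.copy(), k.copy()))

    return Trajectory(np.asarray(times), states, grid, params, settings)
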