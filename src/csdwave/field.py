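"""Spatial discretization of the neural field on the 1D propagation axis.

The cortical patch is a segment Q = [-Lx, Lx] carrying N equally spaced
excitatory/inhibitory population pairs coupled to an extracellular potassium
pool.  This module assembles the discretized right-hand side of the model:
nonlocal synaptic interactions (rectangle-rule quadrature of the Gaussian
kernel over Q, no periodic wrap), potassium diffusion (central second
difference, no-flux Neumann closure), the focal potassium-puff stimulus, and
the full coupled rhs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .transfer import (
    PotassiumDriveParams,
    PotassiumProductionParams,
    TransferParams,
    connectivity_kernel,
    firing_rate,
    potassium_drive,
    rate_to_potassium,
    reference_rate,
)

__all__ = [
    "Grid",
    "CouplingParams",
    "StimulusParams",
    "FieldState",
    "ModelParameters",
    "build_grid",
    "interaction_matrix",
    "interaction",
    "laplacian",
    "stimulus_profile",
    "rhs",
]


@dataclass(frozen=True)
class Grid:
    """Uniform grid on the propagation axis Q = [-Lx, Lx].

    ``spacing`` is hx = 2 Lx / (N - 1); node j sits at x_j = -Lx + j hx.
    For odd N the center node N//2 sits exactly at x = 0.
    """

    half_length: float
    n_nodes: int
    spacing: float = dc_field(init=False)
    coords: np.ndarray = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not self.half_length > 0:
            raise ValueError(f"half_length must be > 0, got {self.half_length}")
        hx = 2.0 * self.half_length / (self.n_nodes - 1)
        object.__setattr__(self, "spacing", hx)
        coords = -self.half_length + hx * np.arange(self.n_nodes, dtype=float)
        coords.flags.writeable = False
        object.__setattr__(self, "coords", coords)

    @property
    def center_index(self) -> int:
        return self.n_nodes // 2


def build_grid(half_length: float, n_nodes: int) -> Grid:
    """Construct the 1D grid; see :class:`Grid` for the layout."""
    return Grid(half_length=float(half_length), n_nodes=int(n_nodes))


@dataclass(frozen=True)
class CouplingParams:
    """Synaptic weights, time constant and potassium diffusion constant.

    Weight subscripts follow target-source order: c_ei multiplies the
    inhibitory interaction Si in the excitatory voltage equation.
    c1/c2 weight the excitatory/inhibitory contributions to potassium
    production.
    """

    c_ee: float
    c_ei: float
    c_ie: float
    c_ii: float
    c1: float
    c2: float
    tau: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("c_ee", "c_ei", "c_ie", "c_ii", "c1", "c2", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class StimulusParams:
    """Focal potassium-puff stimulus: Gaussian bump in space, rectangular
    pulse in time, applied to the potassium equation only."""

    amplitude: float
    center: float = 0.0
    width: float = 1.0
    onset: float = 0.0
    duration: float = 0.0
    shape: str = "gaussian-bump"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.shape != "gaussian-bump":
            raise ValueError(f"unknown stimulus shape {self.shape!r}")


@dataclass
class FieldState:
    """Per-node excitatory potential, inhibitory potential and K+ level."""

    ve: np.ndarray
    vi: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.ve = np.asarray(self.ve, dtype=float)
        self.vi = np.asarray(self.vi, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = len(self.ve)
        if len(self.vi) != n or len(self.k) != n:
            raise ValueError("ve, vi, k must have equal length")

    def copy(self) -> "FieldState":
        return FieldState(self.ve.copy(), self.vi.copy(), self.k.copy())


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter record of the field model."""

    transfer_e: TransferParams
    transfer_i: TransferParams
    drive: PotassiumDriveParams
    production: PotassiumProductionParams
    coupling: CouplingParams
    stimulus: StimulusParams

    def __post_init__(self) -> None:
        self.production.validate_against(self.transfer_e)
        self.production.validate_against(self.transfer_i)

    def reference_rates(self) -> tuple[float, float]:
        """(s_e*, s_i*), recomputed from the current transfer parameters."""
        return (
            reference_rate(self.production, self.transfer_e),
            reference_rate(self.production, self.transfer_i),
        )


def interaction_matrix(grid: Grid) -> np.ndarray:
    """Dense quadrature matrix W with W[j, m] = hx * w(x_j - x_m).

    Rectangle-rule discretization of the nonlocal interaction integral over
    the truncated axis Q (no periodic wrap); Toeplitz up to truncation.
    Precomputed once per grid and applied as a matrix-vector product.
    """
    d = grid.coords[:, None] - grid.coords[None, :]
    return grid.spacing * connectivity_kernel(d)


def interaction(rates: np.ndarray, grid: Grid, W: np.ndarray | None = None) -> np.ndarray:
    """Nonlocal interaction S_j = hx * sum_m w(x_j - x_m) rates_m."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) != grid.n_nodes:
        raise ValueError(
            f"rates length {len(rates)} does not match grid n_nodes {grid.n_nodes}"
        )
    if W is None:
        W = interaction_matrix(grid)
    return W @ rates


def laplacian(k: np.ndarray, grid: Grid) -> np.ndarray:
    """Central second difference with no-flux (mirrored ghost) endpoints.

    The Neumann closure makes pure diffusion conserve the discrete potassium
    mass: sum_j laplacian(k)_j = 0 up to rounding.
    """
    k = np.asarray(k, dtype=float)
    n = grid.n_nodes
    if len(k) != n:
        raise ValueError(f"array length {len(k)} does not match grid n_nodes {n}")
    if n < 3:
        raise ValueError("laplacian needs at least 3 nodes")
    hx2 = grid.spacing**2
    out = np.empty_like(k)
    out[1:-1] = (k[:-2] - 2.0 * k[1:-1] + k[2:]) / hx2
    # flux-form sealed ends: the one-sided flux difference makes the
    # discrete mass sum telescope to zero exactly
    out[0] = (k[1] - k[0]) / hx2
    out[-1] = (k[-2] - k[-1]) / hx2
    return out


def stimulus_profile(grid: Grid, t: float, p: StimulusParams) -> np.ndarray:
    """Per-node stimulus input at time t (zero outside the pulse window)."""
    if p.onset <= t < p.onset + p.duration:
        u = (grid.coords - p.center) / p.width
        return p.amplitude * np.exp(-u * u)
    return np.zeros(grid.n_nodes)


def rhs(
    state: FieldState,
    t: float,
    params: ModelParameters,
    grid: Grid,
    W: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dve, dvi, dk) of the coupled field equations.

    Implements, already divided by tau:

        tau dve = -ve + c_ee Se - c_ei Si + gv(ve, k; beta_ve, kv*)
        tau dvi = -vi + c_ie Se - c_ii Si + gv(vi, k; beta_vi, kv*)
        tau dk  = delta lap(k) + c1 gk(se) + c2 gk(si) + I(x, t)

    with Se/Si the kernel-convolved firing rates and gk evaluated against
    the per-population reference rates s* = s(v*, k1*).
    """
    if W is None:
        W = interaction_matrix(grid)
    cp = params.coupling
    pr = params.production
    se = firing_rate(state.ve, state.k, params.transfer_e)
    si = firing_rate(state.vi, state.k, params.transfer_i)
    Se = W @ se
    Si = W @ si
    gv_e = potassium_drive(state.ve, state.k, params.drive.beta_ve, params.drive.kv_star)
    gv_i = potassium_drive(state.vi, state.k, params.drive.beta_vi, params.drive.kv_star)
    se_star, si_star = params.reference_rates()
    with np.errstate(over="ignore"):  # overflow -> inf, caught by the integrator
        production = cp.c1 * rate_to_potassium(se, se_star, pr.a, pr.b, pr.c) + (
            cp.c2 * rate_to_potassium(si, si_star, pr.a, pr.b, pr.c)
        )
    I = stimulus_profile(grid, t, params.stimulus)
    dve = (-state.ve + cp.c_ee * Se - cp.c_ei * Si + gv_e) / cp.tau
    dvi = (-state.vi + cp.c_ie * Se - cp.c_ii * Si + gv_i) / cp.tau
    dk = (cp.delta * laplacian(state.k, grid) + production + I) / cp.tau
    return dve, dvi, dk
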