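"""Nonlinear transfer functions of the potassium-coupled neural field.

Three nonlinearities couple population voltage and extracellular potassium:

* :func:`firing_rate` — the three-regime firing-rate transfer function
  s_alpha(v, k).  Below the lower potassium threshold k1* the population
  fires on a sigmoid capped at 1/2 (normal activity); between k1* and k2*
  the cap doubles to 1 (potassium-driven hyperactivity); above k2* the
  population is in depolarization block and the rate is exactly 0.
* :func:`potassium_drive` — gv(v, k), the sigmoidal depolarizing drive that
  elevated extracellular potassium exerts on a population's mean voltage.
* :func:`rate_to_potassium` — gk(s, s*), the cosh-shaped rate of potassium
  release into the extracellular space produced by population firing.

The spatial connectivity kernel w(d) = (1/2) exp(-d^2) used by the nonlocal
interaction integrals also lives here, as :func:`connectivity_kernel`.

All functions are pure, vectorize elementwise over NumPy arrays and raise
``ValueError`` on non-finite input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransferParams",
    "PotassiumDriveParams",
    "PotassiumProductionParams",
    "firing_rate",
    "potassium_drive",
    "rate_to_potassium",
    "reference_rate",
    "connectivity_kernel",
]

# Sigmoid arguments are clipped here before exponentiation.  exp(-500) is
# ~7e-218, so clipping changes no value by more than 1e-217 — far below the
# 1e-15 fidelity bound we guarantee — while ruling out overflow warnings.
_EXP_CLIP = 500.0


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXP_CLIP, _EXP_CLIP)))


def _require_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in argument {name!r}")


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the firing-rate transfer function for one population.

    Attributes
    ----------
    beta : float
        Sharpness of the voltage sigmoid (> 0).
    h : float
        Half-response voltage (model voltage units).
    k1_star : float
        Lower potassium threshold (> 0); above it the rate cap doubles.
    k2_star : float
        Upper potassium threshold (> k1_star); above it the population is
        in depolarization block.
    """

    beta: float
    h: float
    k1_star: float
    k2_star: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.k1_star > 0:
            raise ValueError(f"k1_star must be > 0, got {self.k1_star}")
        if not self.k2_star > self.k1_star:
            raise ValueError(
                f"k2_star must exceed k1_star, got k2_star={self.k2_star} "
                f"<= k1_star={self.k1_star}"
            )


@dataclass(frozen=True)
class PotassiumDriveParams:
    """Parameters of the potassium-to-voltage drive gv for both populations."""

    beta_ve: float
    beta_vi: float
    kv_star: float

    def __post_init__(self) -> None:
        if not self.beta_ve > 0:
            raise ValueError(f"beta_ve must be > 0, got {self.beta_ve}")
        if not self.beta_vi > 0:
            raise ValueError(f"beta_vi must be > 0, got {self.beta_vi}")


@dataclass(frozen=True)
class PotassiumProductionParams:
    """Parameters of the firing-rate-to-potassium production function gk.

    ``a`` is the baseline production scale (the minimum of gk), ``b`` the
    cosh sharpness, ``c`` the reference-rate multiplier and ``v_star`` the
    reference voltage at which the reference rate s* = s(v*, k1*) is
    evaluated.  ``c1``/``c2`` weights of the excitatory and inhibitory
    contributions live with the coupling parameters, not here.
    """

    a: float
    b: float
    c: float
    v_star: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")

    def validate_against(self, p: TransferParams) -> None:
        """Check the v* > h invariant against a population's TransferParams."""
        if not self.v_star > p.h:
            raise ValueError(
                f"v_star must exceed the half-response voltage h, got "
                f"v_star={self.v_star} <= h={p.h}"
            )


def firing_rate(v, k, p: TransferParams):
    """Three-regime firing-rate transfer function s_alpha(v, k).

    Parameters
    ----------
    v, k : array_like
        Mean membrane potential and extracellular potassium concentration;
        broadcast elementwise.
    p : TransferParams
        Population parameters (beta, h, k1*, k2*).

    Returns
    -------
    ndarray or float
        Rate in [0, 1].  Branches: k < k1* → sigmoid capped at 1/2;
        k1* <= k <= k2* → sigmoid capped at 1 (both boundary points belong
        to this middle branch); k > k2* → 0 (depolarization block).
    """
    v = np.asarray(v, dtype=float)
    k = np.asarray(k, dtype=float)
    _require_finite("v", v)
    _require_finite("k", k)
    sig = _sigmoid(p.beta * (v - p.h))
    out = np.where(k < p.k1_star, 0.5 * sig, np.where(k <= p.k2_star, sig, 0.0))
    return out if out.ndim else float(out)


def potassium_drive(v, k, beta_v: float, kv_star: float):
    """Potassium-to-voltage drive gv = 1 / (1 + exp(-beta_v (k - kv_star))).

    ``v`` is accepted for signature parity with the field equations but does
    not enter the formula; the drive depends on potassium only.  Strictly
    increasing in ``k``, with gv(kv*) = 1/2.
    """
    if not beta_v > 0:
        raise ValueError(f"beta_v must be > 0, got {beta_v}")
    k = np.asarray(k, dtype=float)
    _require_finite("k", k)
    if v is not None:
        _require_finite("v", np.asarray(v, dtype=float))
    out = _sigmoid(beta_v * (k - kv_star))
    return out if out.ndim else float(out)


def rate_to_potassium(s, s_star, a: float, b: float, c: float):
    """Potassium production gk(s, s*) = a cosh(b (s - c s*)).

    Even about s = c s*, with minimum value ``a`` attained there; production
    grows exponentially as the rate departs from the reference level.
    """
    if not a > 0:
        raise ValueError(f"a must be > 0, got {a}")
    if b < 0 or c < 0:
        raise ValueError(f"b and c must be >= 0, got b={b}, c={c}")
    s = np.asarray(s, dtype=float)
    _require_finite("s", s)
    _require_finite("s_star", np.asarray(s_star, dtype=float))
    arg = np.clip(b * (s - c * np.asarray(s_star, dtype=float)), -700.0, 700.0)
    out = a * np.cosh(arg)
    return out if out.ndim else float(out)


def reference_rate(prod: PotassiumProductionParams, p: TransferParams) -> float:
    """Reference rate s* = s_alpha(v*, k1*) for one population.

    Recomputed from the current parameters on every call — never cached —
    so it can not go stale when TransferParams change.  k = k1* falls on
    the middle (cap 1) branch.
    """
    prod.validate_against(p)
    return float(firing_rate(prod.v_star, p.k1_star, p))


def connectivity_kernel(d):
    """Spatial connectivity kernel w(d) = (1/2) exp(-d^2).

    ``d`` is the signed distance between two grid positions in grid
    coordinates.  Even in ``d``; maximum 1/2 at d = 0.
    """
    d = np.asarray(d, dtype=float)
    _require_finite("d", d)
    out = 0.5 * np.exp(-d * d)
    return out if out.ndim else float(out)
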