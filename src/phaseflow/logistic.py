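"""Deterministic logistic growth analytics.

Closed-form solution of the logistic growth equation (LGE)

    dx/dt = r x (1 - x/K),    x(0) = x0,

its first derivative (the effective growth rate) and second derivative
(growth acceleration), and the geometry of the four growth phases.  Phase
boundaries are the times s1 < s2 < s3 < s4 where the acceleration curve
crosses half its maximum (s1, s2, bracketing the acceleration peak) and half
its minimum (s3, s4, bracketing the deceleration trough).  The resulting
windows are

    acceleration (incl. lag) : t <  s2
    mid-log                  : s2 <= t < s3
    deceleration             : s3 <= t < s4
    stationary               : t >= s4

with boundary ties assigned to the later phase.  All times are measured
from the point where the curve passes through x0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GrowthParams",
    "GrowthPhase",
    "PhaseBoundaries",
    "BoundaryConstructionError",
    "logistic_solution",
    "logistic_rate",
    "logistic_acceleration",
    "time_of_abundance",
    "compute_phase_boundaries",
    "assign_phase",
]

# Normalized abundances u = x/K at the extrema of the acceleration curve
# f(u) = u(1-u)(1-2u): roots of the third derivative.
U_PEAK = (3.0 - math.sqrt(3.0)) / 6.0
U_TROUGH = (3.0 + math.sqrt(3.0)) / 6.0


class GrowthPhase(str, enum.Enum):
    """The four growth phases; lag is folded into acceleration."""

    ACCELERATION = "acceleration"
    MIDLOG = "midlog"
    DECELERATION = "deceleration"
    STATIONARY = "stationary"


@dataclass(frozen=True)
class GrowthParams:
    """Deterministic logistic parameters.

    Parameters
    ----------
    r : float
        Maximal per-capita growth rate (per unit time, > 0).
    K : float
        Carrying capacity (abundance units, > 0).
    x0 : float
        Initial abundance. Canonical sigmoidal curves need 0 < x0 < K;
        x0 > K is accepted by the solution (decay toward K) but rejected
        by phase-boundary construction.
    """

    r: float
    K: float
    x0: float

    def __post_init__(self) -> None:
        for name in ("r", "K", "x0"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"GrowthParams.{name} must be finite and > 0, got {v!r}")


class BoundaryConstructionError(ValueError):
    """Raised when the half-max/half-min crossings cannot be constructed."""


@dataclass(frozen=True)
class PhaseBoundaries:
    """Phase-boundary times and the acceleration levels defining them.

    s1, s2 bracket the acceleration peak at level a_peak/2; s3, s4 bracket
    the trough at level a_trough/2.  Boundary times can be negative when the
    curve starts past a crossing abundance (x0 above the crossing); the
    ordering s1 < s2 < s3 < s4 always holds.
    """

    s1: float
    s2: float
    s3: float
    s4: float
    a_peak: float
    a_trough: float

    @property
    def a_halfmax(self) -> float:
        return self.a_peak / 2.0

    @property
    def a_halfmin(self) -> float:
        return self.a_trough / 2.0

    def window(self, phase: GrowthPhase) -> tuple[float, float]:
        """Half-open time window [lo, hi) occupied by ``phase``."""
        phase = GrowthPhase(phase)
        if phase is GrowthPhase.ACCELERATION:
            return (-math.inf, self.s2)
        if phase is GrowthPhase.MIDLOG:
            return (self.s2, self.s3)
        if phase is GrowthPhase.DECELERATION:
            return (self.s3, self.s4)
        return (self.s4, math.inf)


def _as_array(times) -> tuple[np.ndarray, bool]:
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    return t, (t.ndim == 0)


def logistic_solution(params: GrowthParams, times):
    """Closed-form logistic curve x(t) with x(0) = x0.

    Evaluated as K / (1 + ((K - x0)/x0) e^{-rt}) for t >= 0 so that no
    growing exponential is ever formed; the mirrored form is used for t < 0.
    Returns a float for scalar input, else an ndarray.
    """
    t, scalar = _as_array(times)
    r, K, x0 = params.r, params.K, params.x0
    A = (K - x0) / x0
    tt = np.atleast_1d(t)
    out = np.empty_like(tt)
    fwd = tt >= 0
    out[fwd] = K / (1.0 + A * np.exp(-r * tt[fwd]))
    if np.any(~fwd):
        # t < 0: e^{rt} < 1, so this form cannot overflow either.
        e = np.exp(r * tt[~fwd])
        out[~fwd] = x0 * K * e / ((K - x0) + x0 * e)
    out = out.reshape(t.shape)
    return float(out) if scalar else out


def logistic_rate(params: GrowthParams, times):
    """First derivative dx/dt = r x (1 - x/K) along the solution."""
    t, scalar = _as_array(times)
    x = np.asarray(logistic_solution(params, t))
    out = params.r * x * (1.0 - x / params.K)
    return float(out) if scalar else out


def logistic_acceleration(params: GrowthParams, times):
    """Second derivative d²x/dt² = r² x (1 - x/K)(1 - 2x/K) along the solution.

    Positive before x = K/2 (acceleration side), zero at x = K/2, negative
    after; one positive peak (at x = K(3-√3)/6) and one negative trough
    (at x = K(3+√3)/6).
    """
    t, scalar = _as_array(times)
    x = np.asarray(logistic_solution(params, t))
    u = x / params.K
    out = params.r**2 * x * (1.0 - u) * (1.0 - 2.0 * u)
    return float(out) if scalar else out


def time_of_abundance(params: GrowthParams, x: float) -> float:
    """Invert the logistic curve: the time t at which x(t) = x (0 < x < K)."""
    r, K, x0 = params.r, params.K, params.x0
    if not (0.0 < x < K):
        raise ValueError(f"abundance must lie strictly between 0 and K, got {x!r}")
    return math.log((K - x0) * x / (x0 * (K - x))) / r


def _shape(u: np.ndarray | float):
    """Dimensionless acceleration shape f(u) = u(1-u)(1-2u), u = x/K."""
    return u * (1.0 - u) * (1.0 - 2.0 * u)


def compute_phase_boundaries(params: GrowthParams) -> PhaseBoundaries:
    """Half-max/half-min crossing times of the acceleration curve.

    The crossing abundances are found by bracketed Brent root-finding on the
    dimensionless shape f(u) = u(1-u)(1-2u) (brackets from the analytic
    extrema), then mapped to times through the closed-form inverse of the
    logistic curve.  Because every positive prefactor of the acceleration
    (r², the K² variant, ...) scales the half levels identically, the
    boundary times do not depend on it.

    Raises
    ------
    BoundaryConstructionError
        If x0 >= K/2: the curve starts past the acceleration peak, so the
        half-max crossings s1 and s2 would not precede the observable curve.
    """
    if params.x0 >= params.K / 2.0:
        raise BoundaryConstructionError(
            f"x0 = {params.x0} >= K/2 = {params.K / 2.0}: the curve starts past the "
            "acceleration peak, so the half-max crossings s1 and s2 cannot be constructed"
        )
    half_peak = _shape(U_PEAK) / 2.0
    half_trough = _shape(U_TROUGH) / 2.0
    eps = 1e-12
    u1 = brentq(lambda u: _shape(u) - half_peak, eps, U_PEAK, xtol=1e-15, rtol=8.9e-16)
    u2 = brentq(lambda u: _shape(u) - half_peak, U_PEAK, 0.5, xtol=1e-15, rtol=8.9e-16)
    u3 = brentq(lambda u: _shape(u) - half_trough, 0.5, U_TROUGH, xtol=1e-15, rtol=8.9e-16)
    u4 = brentq(lambda u: _shape(u) - half_trough, U_TROUGH, 1.0 - eps, xtol=1e-15, rtol=8.9e-16)
    s = [time_of_abundance(params, params.K * u) for u in (u1, u2, u3, u4)]
    scale = params.r**2 * params.K
    return PhaseBoundaries(
        s1=s[0],
        s2=s[1],
        s3=s[2],
        s4=s[3],
        a_peak=scale * _shape(U_PEAK),
        a_trough=scale * _shape(U_TROUGH),
    )


def assign_phase(t: float, boundaries: PhaseBoundaries) -> GrowthPhase:
    """Phase of the curve at time ``t`` (half-open windows, ties to the later phase)."""
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if t < boundaries.s2:
        return GrowthPhase.ACCELERATION
    if t < boundaries.s3:
        return GrowthPhase.MIDLOG
    if t < boundaries.s4:
        return GrowthPhase.DECELERATION
    return GrowthPhase.STATIONARY
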