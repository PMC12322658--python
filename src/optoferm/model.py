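"""Monod-type batch kinetics of light-inducible protein production.

The process model tracks three dynamic states — cell density ``c_b`` (OD,
arbitrary units), intracellular protein ``c_p`` (fluorescence, arbitrary
units) and glucose ``c_g`` (g/L) — for a strain carrying a fixed number
``n`` of copies of the EL222 photosensitive transcription factor, grown
under a constant blue-light intensity:

    dc_b/dt = mu * c_b
    dc_p/dt = q_p - (q_d + mu) * c_p
    dc_g/dt = -q_g * c_b
    dn/dt   = 0

with Monod growth ``mu = mu_max * c_g / (c_g + k_g)``, growth-coupled
production ``q_p = alpha * mu / (beta + mu)``, constant first-order
degradation ``q_d = d_p`` and growth-proportional substrate uptake
``q_g = Y_gb * mu``.  The six kinetic parameters depend on light intensity
and EL222 copy number; they are supplied externally (per-condition fits or
a Gaussian-process surrogate, see :mod:`optoferm.gp`).

The copy number is a constant of the motion (it identifies the strain), so
it is carried alongside the three integrated states rather than wasting a
solver dimension on a zero derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Condition",
    "KineticParams",
    "StateVector",
    "Trajectory",
    "SimulationError",
    "specific_growth_rate",
    "production_rate",
    "degradation_rate",
    "uptake_rate",
    "rhs",
    "simulate",
]

#: Default integration tolerances (stiff-capable adaptive solver).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

PARAM_NAMES = ("mu_max", "k_g", "alpha", "beta", "d_p", "y_gb")


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class Condition:
    """A strain x dose experimental condition.

    Parameters
    ----------
    light_intensity:
        Photon flux density of the blue-light panel, μmol m⁻² s⁻¹, >= 0.
    copy_number:
        Number of integrated EL222 cassettes; a non-negative integer.
        Floats are accepted only when exactly integral (no silent rounding).
    """

    light_intensity: float
    copy_number: int

    def __post_init__(self):
        if not math.isfinite(self.light_intensity) or self.light_intensity < 0:
            raise ValueError(f"light_intensity must be finite and >= 0, got {self.light_intensity}")
        cn = self.copy_number
        if isinstance(cn, float):
            if not cn.is_integer():
                raise ValueError(f"copy_number must be an integer, got {cn}")
            object.__setattr__(self, "copy_number", int(cn))
        elif not isinstance(cn, (int, np.integer)):
            raise TypeError(f"copy_number must be an integer, got {type(cn).__name__}")
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {cn}")


@dataclass(frozen=True)
class KineticParams:
    """The six kinetic parameters of the batch model.

    mu_max : maximum specific growth rate, 1/h
    k_g    : glucose half-saturation constant, g/L
    alpha  : maximum specific production rate, fluorescence a.u./h
    beta   : growth-rate half-saturation of production, 1/h
    d_p    : first-order protein degradation rate, 1/h
    y_gb   : substrate-per-biomass yield coefficient, (g/L)/OD
    """

    mu_max: float
    k_g: float
    alpha: float
    beta: float
    d_p: float
    y_gb: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{f.name} must be strictly positive and finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "KineticParams":
        return cls(*(float(v) for v in theta))


@dataclass(frozen=True)
class StateVector:
    """Instantaneous process state (c_b, c_p, c_g) plus the constant n."""

    c_b: float
    c_p: float
    c_g: float
    n: int = 0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.c_b, self.c_p, self.c_g)):
            raise ValueError("state components must be finite")
        if self.c_b <= 0:
            raise ValueError(f"cell density must be > 0, got {self.c_b}")
        if self.c_p < 0:
            raise ValueError(f"protein concentration must be >= 0, got {self.c_p}")
        if self.c_g < 0:
            raise ValueError(f"glucose concentration must be >= 0, got {self.c_g}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_b, self.c_p, self.c_g], dtype=float)


@dataclass
class Trajectory:
    """A simulated (or measured) time course under one condition.

    ``times`` is a strictly increasing grid in hours starting at t0; the
    state arrays are aligned with it, and ``copy_number`` is constant by
    construction.
    """

    times: np.ndarray
    c_b: np.ndarray
    c_p: np.ndarray
    c_g: np.ndarray
    condition: Condition
    params: KineticParams | None = None
    replicate: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.c_b = np.asarray(self.c_b, dtype=float)
        self.c_p = np.asarray(self.c_p, dtype=float)
        self.c_g = np.asarray(self.c_g, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.times.size

    def state_at(self, index: int) -> StateVector:
        return StateVector(
            c_b=float(self.c_b[index]),
            c_p=float(max(self.c_p[index], 0.0)),
            c_g=float(max(self.c_g[index], 0.0)),
            n=self.condition.copy_number,
        )


# ---------------------------------------------------------------------------
# Kinetic laws
# ---------------------------------------------------------------------------

def specific_growth_rate(c_g: float, params: KineticParams) -> float:
    """Monod growth law mu = mu_max * c_g / (c_g + k_g), in 1/h."""
    if np.any(np.asarray(c_g) < 0):
        raise ValueError(f"glucose concentration must be >= 0, got {c_g}")
    return params.mu_max * c_g / (c_g + params.k_g)


def production_rate(mu: float, params: KineticParams) -> float:
    """Specific production rate q_p = alpha * mu / (beta + mu), a.u./h.

    Saturating in the growth rate: production shuts off in stationary
    phase and approaches ``alpha`` at fast growth.
    """
    if np.any(np.asarray(mu) < 0):
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    return params.alpha * mu / (params.beta + mu)


def degradation_rate(params: KineticParams) -> float:
    """Constant first-order protein degradation rate q_d = d_p, 1/h."""
    return params.d_p


def uptake_rate(mu: float, params: KineticParams) -> float:
    """Specific substrate uptake q_g = Y_gb * mu, (g/L) per OD per h."""
    if np.any(np.asarray(mu) < 0):
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    return params.y_gb * mu


def rhs(state: StateVector, params: KineticParams) -> np.ndarray:
    """Right-hand side [dc_b, dc_p, dc_g, dn] of the batch model.

    The fourth component is exactly zero: copy number is fixed per strain.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    d = _rhs_raw(y, params)
    return np.append(d, 0.0)


def _rhs_raw(y: np.ndarray, params: KineticParams) -> np.ndarray:
    c_b, c_p, c_g = y
    c_g = max(c_g, 0.0)  # guard against solver undershoot inside steps
    mu = params.mu_max * c_g / (c_g + params.k_g)
    q_p = params.alpha * mu / (params.beta + mu)
    return np.array([
        mu * c_b,
        q_p - (params.d_p + mu) * c_p,
        -params.y_gb * mu * c_b,
    ])


def _jac_raw(y: np.ndarray, params: KineticParams) -> np.ndarray:
    c_b, c_p, c_g = y
    c_g = max(c_g, 0.0)
    mu = params.mu_max * c_g / (c_g + params.k_g)
    dmu = params.mu_max * params.k_g / (c_g + params.k_g) ** 2
    dqp = params.alpha * params.beta / (params.beta + mu) ** 2  # dq_p/dmu
    return np.array([
        [mu, 0.0, c_b * dmu],
        [0.0, -(params.d_p + mu), (dqp - c_p) * dmu],
        [-params.y_gb * mu, 0.0, -params.y_gb * c_b * dmu],
    ])


def simulate(
    initial: StateVector,
    params: KineticParams,
    times: np.ndarray,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    condition: Condition | None = None,
) -> Trajectory:
    """Integrate the batch model over a strictly increasing time grid.

    The first grid point is the initial time; the returned trajectory
    starts exactly at ``initial``.  Glucose is analytically nonnegative
    under Monod kinetics, so no event handling is needed; output
    undershoots within the solver's local-error scale
    (10 * (atol + rtol * max|y0|)) are clamped to 0, anything more
    negative raises.

    The conservation law c_g + Y_gb*c_b = const holds along exact
    solutions and is preserved to integration tolerance.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid with >= 2 points")

    y0 = initial.as_array()
    sol = solve_ivp(
        lambda t, y: _rhs_raw(y, params),
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=(lambda t, y: _jac_raw(y, params)) if method in ("LSODA", "Radau", "BDF") else None,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise SimulationError(f"ODE solver failed at t={t_fail:.4g} h: {sol.message}", time=t_fail)

    c_b, c_p, c_g = sol.y
    # undershoot scales with the solver's local error, i.e. rtol * state size
    clamp = 10.0 * (atol + rtol * float(np.max(np.abs(y0))))
    if np.any(c_g < -clamp):
        worst = float(c_g.min())
        raise SimulationError(f"glucose went negative beyond tolerance ({worst:.3g} g/L)")
    c_g = np.clip(c_g, 0.0, None)
    c_p = np.where((c_p < 0) & (c_p > -clamp), 0.0, c_p)

    cond = condition if condition is not None else Condition(0.0, initial.n)
    return Trajectory(times=times, c_b=c_b, c_p=c_p, c_g=c_g, condition=cond, params=params)
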