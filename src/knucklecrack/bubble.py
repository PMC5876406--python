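"""Rayleigh-Plesset dynamics of the cavitation bubble.

A spherical bubble of radius ``R(t)`` in an incompressible liquid under a
time-varying ambient pressure ``p(t)`` obeys

    (P_v - p(t))/rho + (p_G0/rho) (R0/R)^{3k}
        = R R'' + 3/2 R'^2 + 4 nu R'/R + 2 S/(rho R)

with vapour pressure ``P_v``, polytropic gas of index ``k`` and initial
partial pressure ``p_G0``, kinematic viscosity ``nu`` and surface tension
``S``.  The equation is stiff for the pressure histories arising in a
cracking joint; it is integrated here in non-dimensional variables (length
scale ``l``, time scale ``tau``, force scale ``w0``) with an implicit stiff
scheme, and re-dimensionalized on return.

A run that ends in step-size collapse, a vanishing radius, an unbounded wall
velocity or runaway growth is classified as *diverged*; this is a result
(used by the limiting-load search), not an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, InceptionError
from .pressure import PressureTrace

__all__ = [
    "FluidProperties",
    "BubbleParams",
    "BubbleTrajectory",
    "NondimScales",
    "RPResult",
    "initial_gas_pressure",
    "nondimensional_coefficients",
    "integrate_rayleigh_plesset",
    "wall_acceleration",
]

# Divergence thresholds (dimensional, SI).
R_MIN_DIVERGED = 1e-9      # m: radius collapsed to nothing
RDOT_MAX_DIVERGED = 1e3    # m/s: unbounded wall velocity
R_MAX_DIVERGED = 5e-3      # m: bubble grown past the joint scale


@dataclass(frozen=True)
class FluidProperties:
    """Physical properties of the liquid surrounding the bubble.

    Defaults are the synovial-fluid values: density 1015 kg/m^3, low-shear
    dynamic viscosity 0.4 Pa s, surface tension 46.7 mN/m, vapour pressure
    6500 Pa, and the adiabatic index of CO2 (1.3) for the entrapped gas.
    """

    rho: float = 1015.0
    mu: float = 0.4
    surface_tension: float = 0.0467
    vapor_pressure: float = 6500.0
    polytropic_index: float = 1.3

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "surface_tension", "vapor_pressure",
                     "polytropic_index"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"{name} must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity ``mu / rho`` (m^2/s)."""
        return self.mu / self.rho


def initial_gas_pressure(p0: float, fluid: FluidProperties, r0: float) -> float:
    """Initial gas partial pressure from the surface-tension balance.

    A bubble of radius ``r0`` in equilibrium with ambient pressure ``p0``
    satisfies ``p_G0 = p0 - P_v + 2 S / r0``.

    Raises
    ------
    InceptionError
        If the balance would require negative gas pressure
        (``p0 < P_v - 2S/r0``); the caller should re-anchor ``p0``.
    """
    if r0 <= 0.0:
        raise DomainError("initial radius must be positive")
    p_go = p0 - fluid.vapor_pressure + 2.0 * fluid.surface_tension / r0
    if p_go < 0.0:
        raise InceptionError(
            f"equilibrium impossible: p0={p0} below "
            f"P_v - 2S/R0 = {fluid.vapor_pressure - 2*fluid.surface_tension/r0}; "
            "re-anchor the inception pressure (e.g. to the vapour pressure)"
        )
    return p_go


@dataclass(frozen=True)
class BubbleParams:
    """Initial bubble state: radius, gas partial pressure, anchor pressure."""

    r0: float = 200e-6
    p_go: float = 0.0
    p0: float = 101325.0

    def __post_init__(self) -> None:
        if self.r0 <= 0.0:
            raise DomainError("initial radius must be positive")
        if self.p_go < 0.0:
            raise DomainError("initial gas pressure cannot be negative")

    @classmethod
    def at_equilibrium(
        cls, p0: float, fluid: FluidProperties, r0: float = 200e-6
    ) -> "BubbleParams":
        """Bubble in mechanical equilibrium with ambient ``p0``."""
        return cls(r0=r0, p_go=initial_gas_pressure(p0, fluid, r0), p0=p0)


@dataclass(frozen=True)
class NondimScales:
    """Reference scales of the non-dimensional formulation.

    Lengths scale with the typical joint separation (1 mm), times with the
    duration of a crack (10 ms) and forces with the external load at which a
    knuckle cracks (100 N), giving ``w0/l^2`` as the pressure scale.
    """

    l: float = 1e-3
    tau: float = 1e-2
    w0: float = 100.0

    def __post_init__(self) -> None:
        for name in ("l", "tau", "w0"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"scale {name} must be positive")

    @property
    def pressure_scale(self) -> float:
        return self.w0 / self.l**2


def nondimensional_coefficients(
    fluid: FluidProperties, scales: NondimScales = NondimScales()
) -> dict:
    """Coefficients of the non-dimensional Rayleigh-Plesset equation.

    Returns ``C_press = w0 tau^2/(rho l^4)`` (pressure/inertia group),
    ``C_visc = 4 nu tau/l^2`` and ``C_surf = 2 S tau^2/(rho l^3)``.
    """
    return {
        "C_press": scales.w0 * scales.tau**2 / (fluid.rho * scales.l**4),
        "C_visc": 4.0 * fluid.nu * scales.tau / scales.l**2,
        "C_surf": 2.0 * fluid.surface_tension * scales.tau**2
        / (fluid.rho * scales.l**3),
    }


@dataclass
class BubbleTrajectory:
    """Bubble radius, wall velocity and wall acceleration versus time."""

    t: np.ndarray
    r: np.ndarray
    rdot: np.ndarray
    rddot: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.rdot = np.asarray(self.rdot, dtype=float)
        if self.rddot is not None:
            self.rddot = np.asarray(self.rddot, dtype=float)

    def to_frame(self):
        import pandas as pd

        data = {"t_s": self.t, "R_m": self.r, "Rdot_m_s": self.rdot}
        if self.rddot is not None:
            data["Rddot_m_s2"] = self.rddot
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RPResult:
    """Outcome of a Rayleigh-Plesset integration.

    ``converged`` is False when the run is classified as diverged; the
    (possibly truncated) trajectory is still returned for inspection.
    """

    trajectory: BubbleTrajectory
    converged: bool
    reason: Optional[str] = None
    dense: Optional[Callable] = None  # t -> (R, Rdot), dimensional


def wall_acceleration(traj: BubbleTrajectory) -> np.ndarray:
    """Wall acceleration by backward differences of the wall velocity.

    ``Rddot[i] = (Rdot[i] - Rdot[i-1]) / (t[i] - t[i-1])``; the first point
    copies the second (no forward information is used).  The trajectory's
    ``rddot`` field is populated and the array returned.
    """
    t, rdot = traj.t, traj.rdot
    if len(t) < 3:
        raise DomainError("need at least 3 points to differentiate")
    dt = np.diff(t)
    if np.any(dt <= 0.0):
        raise DomainError("time grid must be strictly increasing")
    rddot = np.empty_like(rdot)
    rddot[1:] = np.diff(rdot) / dt
    rddot[0] = rddot[1]
    traj.rddot = rddot
    return rddot


def _forcing_callable(forcing) -> Callable:
    if callable(forcing):
        return forcing
    if isinstance(forcing, PressureTrace):
        t, p = forcing.t, forcing.p_amb
        return lambda tt: np.interp(tt, t, p)
    raise DomainError("forcing must be a callable p(t) or a PressureTrace")


def integrate_rayleigh_plesset(
    forcing: Union[Callable, PressureTrace],
    fluid: FluidProperties,
    bubble: BubbleParams,
    t_end: float = 0.01,
    rtol: float = 1e-7,
    atol: float = 1e-7,
    method: str = "Radau",
    scales: NondimScales = NondimScales(),
    dimensional: bool = False,
    stop_at_rebound: bool = False,
    max_step_fraction: float = 1.0 / 400.0,
    dense: bool = False,
) -> RPResult:
    """Integrate the Rayleigh-Plesset equation under ``forcing``.

    Initial conditions are ``R(0) = r0`` and ``Rdot(0) = 0``.  By default the
    equation is solved in the non-dimensional variables (``dimensional=True``
    solves the raw SI form, used as a consistency cross-check).  ``method``
    is any stiff ``solve_ivp`` method (``"Radau"`` default, ``"BDF"`` for the
    dual-solver comparison).

    Divergence (step failure, ``R < 1e-9`` m, ``|Rdot| > 1e3`` m/s, or growth
    beyond the joint scale) is reported through ``RPResult.converged`` /
    ``RPResult.reason`` rather than raised.
    """
    if t_end <= 0.0:
        raise DomainError("t_end must be positive")
    p_of_t = _forcing_callable(forcing)
    rho, nu, s_t = fluid.rho, fluid.nu, fluid.surface_tension
    p_v, k = fluid.vapor_pressure, fluid.polytropic_index
    r0, p_go = bubble.r0, bubble.p_go
    if p_go < 0.0:
        raise DomainError("initial gas pressure cannot be negative")

    if dimensional:
        lsc = tsc = 1.0
        psc = 1.0
    else:
        lsc, tsc = scales.l, scales.tau
        psc = scales.pressure_scale

    cp = psc * tsc**2 / (rho * lsc**2)       # pressure group in scaled vars
    cv = 4.0 * nu * tsc / lsc**2
    cs = 2.0 * s_t * tsc**2 / (rho * lsc**3)
    r0n = r0 / lsc
    pvn, pgon = p_v / psc, p_go / psc

    def rhs(tn, y):
        rn, rdn = y
        pn = p_of_t(tn * tsc) / psc
        gas = pgon * (r0n / rn) ** (3.0 * k)
        rddn = (
            cp * (pvn - pn + gas) / rn
            - 1.5 * rdn * rdn / rn
            - cv * rdn / (rn * rn)
            - cs / (rn * rn)
        )
        return (rdn, rddn)

    def ev_tiny(tn, y):
        return y[0] - R_MIN_DIVERGED / lsc

    def ev_fast(tn, y):
        return abs(y[1]) - RDOT_MAX_DIVERGED * tsc / lsc

    def ev_huge(tn, y):
        return y[0] - R_MAX_DIVERGED / lsc

    for ev in (ev_tiny, ev_fast, ev_huge):
        ev.terminal = True
    events = [ev_tiny, ev_fast, ev_huge]

    if stop_at_rebound:
        def ev_rebound(tn, y):
            return y[1]
        ev_rebound.terminal = True
        ev_rebound.direction = 1.0
        events.append(ev_rebound)

    sol = solve_ivp(
        rhs,
        (0.0, t_end / tsc),
        (r0n, 0.0),
        method=method,
        rtol=rtol,
        atol=atol,
        max_step=(t_end / tsc) * max_step_fraction,
        events=events,
        dense_output=dense,
    )

    t = sol.t * tsc
    r = sol.y[0] * lsc
    rdot = sol.y[1] * lsc / tsc
    traj = BubbleTrajectory(t=t, r=r, rdot=rdot)
    if len(t) >= 3:
        wall_acceleration(traj)

    reason = None
    stopped_at_rebound = stop_at_rebound and len(sol.t_events[3]) > 0
    if not sol.success:
        reason = "integrator step failure"
    elif len(sol.t_events[0]) > 0:
        reason = "radius collapsed below 1e-9 m"
    elif len(sol.t_events[1]) > 0:
        reason = "wall speed exceeded 1e3 m/s"
    elif len(sol.t_events[2]) > 0:
        reason = "runaway growth beyond the joint scale"
    elif not stopped_at_rebound and t[-1] < t_end * (1.0 - 1e-9):
        reason = "integration terminated early"

    dense_fn = None
    if dense and sol.sol is not None:
        def dense_fn(tq, _s=sol.sol, _l=lsc, _t=tsc):
            out = _s(np.asarray(tq) / _t)
            return out[0] * _l, out[1] * _l / _t

    return RPResult(
        trajectory=traj,
        converged=reason is None,
        reason=reason,
        dense=dense_fn,
    )
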