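"""Idealized 2D geometry and separation kinematics of the MCP joint.

The metacarpal head and the base of the proximal phalanx are approximated by
two circular arcs of radii ``R_m < R_p`` whose centres are offset by the
eccentricity ``e``.  The film thickness between the arcs at angle ``theta``
from the line of centres is ``h = c - e*cos(theta)`` with radial clearance
``c = R_p - R_m``; the central joint gap is ``c - e``.  During an articular
release the joint springs apart with constant acceleration ``a`` so that
``e(t) = e0 - a t^2 / 2``.

All quantities are SI (metres, seconds); converting from the millimetre
values usually quoted for hand anatomy is the caller's job (the CLI/config
layer does it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "JointGeometry",
    "JointKinematics",
    "radial_clearance",
    "initial_eccentricity",
    "eccentricity_at",
    "acceleration_from_spacing",
]


def radial_clearance(r_metacarpal: float, r_phalanx: float) -> float:
    """Radial clearance ``c = R_p - R_m`` between the two arcs (m).

    Raises
    ------
    DomainError
        If either radius is non-positive or the phalanx base radius does not
        exceed the metacarpal head radius (the arcs could not nest).
    """
    if r_metacarpal <= 0.0 or r_phalanx <= 0.0:
        raise DomainError("joint radii must be positive")
    if r_phalanx <= r_metacarpal:
        raise DomainError(
            f"phalanx radius ({r_phalanx}) must exceed metacarpal radius "
            f"({r_metacarpal})"
        )
    return r_phalanx - r_metacarpal


def initial_eccentricity(clearance: float, separation: float) -> float:
    """Eccentricity ``e0 = c - s`` that leaves a central joint gap ``s`` (m).

    ``separation`` is the gap between the articulating surfaces at the onset
    of cracking (1.6 mm in the baseline anatomy).
    """
    if clearance <= 0.0:
        raise DomainError("clearance must be positive")
    if separation < 0.0:
        raise DomainError("separation cannot be negative")
    if separation > clearance:
        raise DomainError(
            f"separation ({separation}) exceeds clearance ({clearance}); "
            "the arcs would not overlap"
        )
    return clearance - separation


def acceleration_from_spacing(delta_d: float, delta_t: float) -> float:
    """Constant acceleration fitted between two joint-spacing measurements.

    A joint starting from rest that covers an extra spacing ``delta_d`` in
    time ``delta_t`` under constant acceleration satisfies
    ``delta_d = a delta_t^2 / 2``, hence ``a = 2 delta_d / delta_t^2``.
    """
    if delta_t <= 0.0:
        raise DomainError("time interval must be positive")
    if delta_d < 0.0:
        raise DomainError("spacing change cannot be negative")
    return 2.0 * delta_d / (delta_t * delta_t)


@dataclass(frozen=True)
class JointGeometry:
    """Two-arc approximation of the MCP joint.

    Parameters
    ----------
    r_metacarpal : float
        Metacarpal head radius ``R_m`` (m).
    r_phalanx : float
        Proximal phalanx base radius ``R_p`` (m).
    theta1 : float
        Half angular sector of the joint (rad), default ``pi/4``.
    """

    r_metacarpal: float = 6.44e-3
    r_phalanx: float = 11.46e-3
    theta1: float = math.pi / 4.0

    def __post_init__(self) -> None:
        radial_clearance(self.r_metacarpal, self.r_phalanx)  # validates radii
        if not 0.0 < self.theta1 < math.pi / 2.0:
            raise DomainError("theta1 must lie in (0, pi/2)")

    @property
    def clearance(self) -> float:
        """Radial clearance ``c = R_p - R_m`` (m)."""
        return radial_clearance(self.r_metacarpal, self.r_phalanx)


@dataclass(frozen=True)
class JointKinematics:
    """Constant-acceleration separation law ``e(t) = e0 - a t^2 / 2``.

    ``e0`` must be consistent with the paired geometry (``0 <= e0 < c``);
    pair construction is validated by :func:`make_kinematics`.
    """

    e0: float
    a: float = 72.0
    t_end: float = 0.01

    def __post_init__(self) -> None:
        if self.e0 < 0.0:
            raise DomainError("initial eccentricity cannot be negative")
        if self.a < 0.0:
            raise DomainError("separation acceleration cannot be negative")
        if self.t_end <= 0.0:
            raise DomainError("simulation horizon must be positive")

    def time_of_zero_eccentricity(self) -> float:
        """Time at which the arcs become concentric (``inf`` if ``a == 0``)."""
        if self.a == 0.0:
            return math.inf
        return math.sqrt(2.0 * self.e0 / self.a)


def make_kinematics(
    geometry: JointGeometry,
    separation: float,
    a: float = 72.0,
    t_end: float = 0.01,
) -> JointKinematics:
    """Build kinematics whose ``e0`` leaves the stated central gap."""
    e0 = initial_eccentricity(geometry.clearance, separation)
    if e0 >= geometry.clearance:
        raise DomainError("initial eccentricity must be below the clearance")
    return JointKinematics(e0=e0, a=a, t_end=t_end)


def eccentricity_at(t: float, kin: JointKinematics, strict: bool = True) -> float:
    """Eccentricity ``e(t) = e0 - a t^2 / 2`` (m).

    With ``strict=True`` (default) a negative result raises
    :class:`DomainError` — the arcs would have crossed concentricity and the
    two-arc picture no longer defines a film.  ``strict=False`` returns the
    analytic continuation, which the pressure module uses internally for the
    short tail of the event after the arcs pass through concentricity.
    """
    if t < 0.0:
        raise DomainError("time must be non-negative")
    e = kin.e0 - 0.5 * kin.a * t * t
    if strict and e < 0.0:
        raise DomainError(
            f"eccentricity is negative at t={t}: joint fully separated"
        )
    return e
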