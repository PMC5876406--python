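"""Tribonucleation squeeze-film pressure in the separating joint.

When two closely apposed, fluid-wetted surfaces are pulled apart, viscous
adhesion generates low pressure in the entrapped film.  For a film between
two spherical surfaces carrying a load ``w`` the pressure drop below the
reference pressure at angular position ``theta`` is

    dp(theta) = w / (2 pi R_m^2 A) * [ 1/(1 - eps cos(theta))^2
                                       - 1/(1 - eps cos(theta1))^2 ]

with ``eps = e/c`` the eccentricity ratio and ``A(eps, theta1)`` a purely
geometric factor (a five-term combination of rational and logarithmic terms).
The drop is largest at the centre ``theta = 0``, which is where cavitation
first occurs and where the bubble of :mod:`knucklecrack.bubble` lives.

Two pressure series are produced for a cracking joint:

``p_film``
    The absolute film pressure ``P_atm - dp(0)`` from the formula as printed.
    At the baseline load this plunges to several atmospheres of tension --
    far below the vapour pressure -- which is the tribonucleation argument
    for bubble inception.  Because the formula describes quasi-static load
    support, ``dp`` tends to a *non-zero* constant as ``eps -> 0`` (the film
    must still carry ``w``), so ``p_film`` does not relax to the zero-load
    pressure on its own.

``p_amb``
    The transient forcing felt by the bubble: the *excess* suction over the
    fully separated (``eps -> 0``) load-support value, scaled by the film
    load fraction ``eta`` (the share of the joint load communicated to the
    central film region; see the methods note), and referenced so that the
    fully separated joint sits at the zero-load pressure ``P_atm``.  This
    trace rises monotonically and saturates at ``P_atm`` within the event,
    and is the ``p(t)`` that enters the Rayleigh-Plesset equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .geometry import JointGeometry, JointKinematics

__all__ = [
    "LoadCase",
    "PressureTrace",
    "geometric_factor_A",
    "pressure_drop",
    "zero_eccentricity_ratio",
    "ambient_pressure_fn",
    "film_pressure_fn",
    "ambient_pressure_series",
    "DEFAULT_LOAD_FRACTION",
]

#: Film load fraction calibrated once against the baseline acoustic
#: signature (dominant frequency) of the reference simulation; see
#: docs/methods.md for the calibration protocol.
DEFAULT_LOAD_FRACTION = 0.6965

# Below this |eps| the five-term A expression loses all significant digits to
# cancellation (terms ~1/eps cancelling to O(eps)), so a quartic Taylor
# series is used instead; the two branches agree to ~1e-9 at the switch.
_SERIES_EPS = 1e-2


def _series_coeffs(theta1: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    c = math.cos(theta1)
    a_coeffs = (
        2.0 / 3.0 - c + c**3 / 3.0,
        0.75 * (1.0 - c * c) ** 2,
        4.0 / 5.0 - 2.0 * c**3 + 1.2 * c**5,
        5.0 / 6.0 - 2.5 * c**4 + (5.0 / 3.0) * c**6,
    )
    b_coeffs = tuple((n + 1.0) * (1.0 - c**n) for n in range(1, 5))
    return a_coeffs, b_coeffs


def _factor_A_direct(eps, theta1: float):
    c = math.cos(theta1)
    s2 = math.sin(theta1) ** 2
    eps = np.asarray(eps, dtype=float)
    return (
        1.0 / (eps * (1.0 - eps))
        + np.log1p(-eps) / eps**2
        - c / (eps * (1.0 - eps * c))
        - np.log1p(-eps * c) / eps**2
        - s2 / (2.0 * (1.0 - eps * c) ** 2)
    )


def _factor_A_series(eps, theta1: float):
    a, _ = _series_coeffs(theta1)
    eps = np.asarray(eps, dtype=float)
    return eps * (a[0] + eps * (a[1] + eps * (a[2] + eps * a[3])))


def geometric_factor_A(eps: float, theta1: float) -> float:
    """Geometric factor ``A`` of the squeeze-film pressure formula.

    Valid for ``0 < eps < 1`` and ``0 < theta1 < pi/2``.  ``A -> 0`` linearly
    as the arcs become concentric and diverges as ``eps -> 1`` (contact).
    Evaluation switches to a quartic series for small ``eps`` where the
    direct expression suffers catastrophic cancellation.
    """
    if not 0.0 < theta1 < math.pi / 2.0:
        raise DomainError("theta1 must lie in (0, pi/2)")
    if not 0.0 < eps < 1.0:
        raise DomainError(f"eccentricity ratio {eps} outside (0, 1)")
    if eps < _SERIES_EPS:
        return float(_factor_A_series(eps, theta1))
    return float(_factor_A_direct(eps, theta1))


def _bracket(eps, theta, theta1: float):
    ct = np.cos(theta)
    c1 = math.cos(theta1)
    return 1.0 / (1.0 - eps * ct) ** 2 - 1.0 / (1.0 - eps * c1) ** 2


def pressure_drop(
    theta: float,
    eps: float,
    w: float,
    r_metacarpal: float,
    theta1: float,
) -> float:
    """Squeeze-film pressure drop (Pa) at angle ``theta`` for load ``w`` (N).

    The drop vanishes identically at ``theta = +/- theta1`` (the film edge is
    the pressure reference) and is maximal at the centre ``theta = 0``.
    Linear in ``w``.
    """
    if abs(theta) > theta1 + 1e-12:
        raise DomainError("theta outside the joint sector [-theta1, theta1]")
    if w <= 0.0:
        raise DomainError("load must be positive")
    if r_metacarpal <= 0.0:
        raise DomainError("metacarpal radius must be positive")
    A = geometric_factor_A(eps, theta1)  # validates eps, theta1
    scale = w / (2.0 * math.pi * r_metacarpal**2 * A)
    return float(scale * _bracket(eps, theta, theta1))


def _central_ratio(eps, theta1: float):
    """``bracket(theta=0)/A`` -- the central drop per unit ``w/(2 pi R_m^2)``.

    Analytic through ``eps = 0`` (both numerator and denominator vanish
    linearly); a quartic-over-quartic series is used for small ``|eps|``.
    """
    eps = np.asarray(eps, dtype=float)
    a, b = _series_coeffs(theta1)
    num_s = b[0] + eps * (b[1] + eps * (b[2] + eps * b[3]))
    den_s = a[0] + eps * (a[1] + eps * (a[2] + eps * a[3]))
    small = np.abs(eps) < _SERIES_EPS
    safe = np.where(small, 0.5, eps)  # dummy away from singular points
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = _bracket(safe, 0.0, theta1) / _factor_A_direct(safe, theta1)
    return np.where(small, num_s / den_s, direct)


def zero_eccentricity_ratio(theta1: float) -> float:
    """Limit of ``bracket(0)/A`` as ``eps -> 0`` (concentric arcs).

    This is the residual load-support level of the printed formula; the
    transient forcing is measured relative to it.
    """
    a, b = _series_coeffs(theta1)
    return b[0] / a[0]


@dataclass(frozen=True)
class LoadCase:
    """Load on the synovial fluid and the ambient reference pressure.

    Parameters
    ----------
    w : float
        Load carried by the synovial fluid (N).
    p_atm : float
        Zero-load reference pressure of the joint (Pa).
    load_fraction : float
        Share ``eta`` of the film suction excess communicated to the bubble
        site (dimensionless, in (0, 1]).  The default is the package's
        calibrated value; see the methods note.
    """

    w: float = 13.0
    p_atm: float = 101325.0
    load_fraction: float = DEFAULT_LOAD_FRACTION

    def __post_init__(self) -> None:
        if self.w <= 0.0:
            raise DomainError("load must be positive")
        if self.p_atm <= 0.0:
            raise DomainError("reference pressure must be positive")
        if not 0.0 < self.load_fraction <= 1.0:
            raise DomainError("load_fraction must lie in (0, 1]")


def _eps_fn(geom: JointGeometry, kin: JointKinematics):
    c = geom.clearance
    e0, a = kin.e0, kin.a
    eps0 = e0 / c
    if not 0.0 <= eps0 < 1.0:
        raise DomainError(f"initial eccentricity ratio {eps0} outside [0, 1)")
    return lambda t: (e0 - 0.5 * a * np.asarray(t, dtype=float) ** 2) / c


def ambient_pressure_fn(geom: JointGeometry, kin: JointKinematics, load: LoadCase):
    """Return the forcing pressure ``p_amb(t)`` as a vectorized callable.

    Evaluated analytically at whatever time points the stiff solver requests
    (no tabulation/interpolation).
    """
    eps = _eps_fn(geom, kin)
    scale = load.load_fraction * load.w / (2.0 * math.pi * geom.r_metacarpal**2)
    r0 = zero_eccentricity_ratio(geom.theta1)
    th1 = geom.theta1

    def p_amb(t):
        return load.p_atm - scale * (_central_ratio(eps(t), th1) - r0)

    return p_amb


def film_pressure_fn(geom: JointGeometry, kin: JointKinematics, load: LoadCase):
    """Absolute film pressure ``P_atm - dp(0, t)`` from the printed formula."""
    eps = _eps_fn(geom, kin)
    scale = load.w / (2.0 * math.pi * geom.r_metacarpal**2)
    th1 = geom.theta1

    def p_film(t):
        return load.p_atm - scale * _central_ratio(eps(t), th1)

    return p_film


@dataclass
class PressureTrace:
    """Time series of the joint-centre pressures.

    Attributes
    ----------
    t : ndarray
        Strictly increasing time grid (s).
    p_amb : ndarray
        Bubble-forcing ambient pressure (Pa); monotone non-decreasing for a
        separating joint, saturating at ``p_atm``.
    p_film : ndarray
        Raw squeeze-film pressure (Pa); may be deeply negative (tension).
    p_atm : float
        Zero-load reference (Pa).
    """

    t: np.ndarray
    p_amb: np.ndarray
    p_film: np.ndarray
    p_atm: float = 101325.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p_amb = np.asarray(self.p_amb, dtype=float)
        self.p_film = np.asarray(self.p_film, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise DomainError("time grid must be 1-D with at least 2 points")
        if not np.all(np.diff(self.t) > 0.0):
            raise DomainError("time grid must be strictly increasing")
        if len(self.p_amb) != len(self.t) or len(self.p_film) != len(self.t):
            raise DomainError("pressure series must match the time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "p_pa": self.p_amb, "p_film_pa": self.p_film}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ambient_pressure_series(
    geom: JointGeometry,
    kin: JointKinematics,
    load: LoadCase,
    t_grid: np.ndarray,
) -> PressureTrace:
    """Evaluate both pressure series on an explicit time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0.0):
        raise DomainError("time grid must be non-negative")
    eps = _eps_fn(geom, kin)(t_grid)
    if np.any(eps >= 1.0):
        i = int(np.argmax(eps >= 1.0))
        raise DomainError(
            f"eccentricity ratio reaches 1 (surface contact) at t={t_grid[i]}"
        )
    p_amb = ambient_pressure_fn(geom, kin, load)(t_grid)
    p_film = film_pressure_fn(geom, kin, load)(t_grid)
    return PressureTrace(t=t_grid, p_amb=p_amb, p_film=p_film, p_atm=load.p_atm)
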