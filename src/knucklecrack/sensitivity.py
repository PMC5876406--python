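"""One-at-a-time sensitivity sweeps, limiting-load search, scale analysis.

The acoustic signature is swept against the film load, joint acceleration,
initial bubble radius, fluid viscosity and joint geometry; the load also
admits a *limiting value* above which the coupled integration no longer
converges, found here by bisection on the converged/diverged boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bubble import FluidProperties, NondimScales, nondimensional_coefficients
from .config import RunConfig
from .errors import BracketError, DomainError
from .pipeline import simulate

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "limiting_load",
    "geometry_sweep",
    "order_of_magnitude_report",
    "SIGMA_METACARPAL_MM",
    "SIGMA_PHALANX_MM",
]

log = logging.getLogger(__name__)

#: Reported anatomical standard deviations of the joint radii (mm).
SIGMA_METACARPAL_MM = 1.08
SIGMA_PHALANX_MM = 2.30

#: parameter name -> (config section, key, unit note)
_PARAMETERS = {
    "load_w": ("load", "w_newton", "N"),
    "acceleration_a": ("joint", "acceleration_m_s2", "m/s^2"),
    "bubble_r0": ("bubble", "r0_um", "um"),
    "viscosity_mu": ("fluid", "mu_pa_s", "Pa s"),
}


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep around a base configuration."""

    parameter: str
    values: Sequence[float]
    config: RunConfig = field(default_factory=RunConfig)

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise DomainError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"choose from {sorted(_PARAMETERS)}"
            )
        if len(self.values) == 0:
            raise DomainError("sweep needs at least one value")
        if any(v <= 0.0 for v in self.values):
            raise DomainError("sweep values must be positive")


@dataclass
class SweepResult:
    """Per-value pipeline outcomes as a tidy table."""

    parameter: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the full pipeline once per parameter value.

    Divergent runs are recorded (``converged=False``, no frequency), never
    raised.  Deterministic given the configuration.
    """
    section, key, unit = _PARAMETERS[spec.parameter]
    rows = []
    for value in spec.values:
        cfg = spec.config.replace_value(section, key, float(value))
        result = simulate(cfg)
        s = result.summary
        rows.append(
            {
                "value": float(value),
                "unit": unit,
                "f_dominant_hz": s["f_dominant_hz"],
                "peak_spl_db": s["peak_spl_db"],
                "converged": s["converged"],
                "min_p_amb_pa": s["min_p_amb_pa"],
                "min_p_film_pa": s["min_p_film_pa"],
            }
        )
        log.info("sweep %s=%g: converged=%s f=%s", spec.parameter, value,
                 s["converged"], s["f_dominant_hz"])
    return SweepResult(parameter=spec.parameter, table=pd.DataFrame(rows))


def _converges(config: RunConfig, w: float) -> bool:
    return simulate(config.replace_value("load", "w_newton", w)).converged


def limiting_load(
    config: RunConfig = RunConfig(),
    w_lo: float = 13.0,
    w_hi: float = 24.0,
    tol: float = 0.25,
) -> dict:
    """Largest load at which the pipeline still converges, by bisection.

    Requires a valid bracket (convergence at ``w_lo``, divergence at
    ``w_hi``); monotonicity of divergence in the load is assumed in between
    and checked at the endpoints.

    Returns a dict with the bracket midpoint ``w_limit``, the final bracket,
    and the bisection resolution.
    """
    if not (0.0 < w_lo < w_hi):
        raise DomainError("need 0 < w_lo < w_hi")
    if tol <= 0.0:
        raise DomainError("tolerance must be positive")
    if not _converges(config, w_lo):
        raise BracketError(f"run already diverges at w_lo={w_lo} N")
    if _converges(config, w_hi):
        raise BracketError(f"run still converges at w_hi={w_hi} N")
    lo, hi = w_lo, w_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _converges(config, mid):
            lo = mid
        else:
            hi = mid
        log.info("limiting-load bracket: [%.3f, %.3f] N", lo, hi)
    return {"w_limit": 0.5 * (lo + hi), "bracket": (lo, hi), "tol": tol}


def geometry_sweep(
    config: RunConfig = RunConfig(),
    sigma_frac: float = 0.5,
    sigma_m_mm: float = SIGMA_METACARPAL_MM,
    sigma_p_mm: float = SIGMA_PHALANX_MM,
) -> SweepResult:
    """Sweep the joint radii over the four ``+/- sigma_frac * sigma`` corners.

    The onset separation is held fixed, so each corner has its own clearance
    ``c = R_p - R_m`` and initial eccentricity ratio ``eps0``.  Corners whose
    geometry is invalid (e.g. separation exceeding the clearance) are
    recorded as invalid rather than raised.
    """
    base_m = config.joint.r_metacarpal_mm
    base_p = config.joint.r_phalanx_mm
    sep = config.joint.separation_mm
    corners = [("baseline", base_m, base_p)]
    if sigma_frac > 0.0:
        for sm in (-sigma_frac, sigma_frac):
            for sp in (-sigma_frac, sigma_frac):
                corners.append(
                    (
                        f"Rm{sm:+.2g}sm_Rp{sp:+.2g}sp",
                        base_m + sm * sigma_m_mm,
                        base_p + sp * sigma_p_mm,
                    )
                )
    rows = []
    for label, rm, rp in corners:
        c_mm = rp - rm
        row = {
            "corner": label,
            "r_metacarpal_mm": rm,
            "r_phalanx_mm": rp,
            "clearance_mm": c_mm,
            "eps0": None,
            "valid": False,
            "converged": None,
            "f_dominant_hz": None,
            "peak_spl_db": None,
        }
        if c_mm > sep and rm > 0.0:
            row["eps0"] = (c_mm - sep) / c_mm
            row["valid"] = True
            cfg = config.replace_value("joint", "r_metacarpal_mm", rm)
            cfg = cfg.replace_value("joint", "r_phalanx_mm", rp)
            result = simulate(cfg)
            row["converged"] = result.converged
            row["f_dominant_hz"] = result.summary["f_dominant_hz"]
            row["peak_spl_db"] = result.summary["peak_spl_db"]
        rows.append(row)
    return SweepResult(parameter="geometry_sigma", table=pd.DataFrame(rows))


def order_of_magnitude_report(
    fluid: FluidProperties = FluidProperties(),
    scales: NondimScales = NondimScales(),
) -> dict:
    """Base-10 orders of the non-dimensional equation's coefficients.

    The pressure coefficient ``C_press = w0 tau^2 / (rho l^4)`` dominates by
    several orders of magnitude, which is why the load and the joint
    kinematics control the dynamics.  Note: with the nominal scales the
    computed order of ``C_press`` is 7, not the smaller order sometimes
    quoted for this group; the report returns computed values only.
    """
    coeffs = nondimensional_coefficients(fluid, scales)
    orders = {k: int(math.floor(math.log10(v))) for k, v in coeffs.items()}
    dominant = max(coeffs, key=coeffs.get)
    others = [v for k, v in coeffs.items() if k != dominant]
    return {
        "coefficients": coeffs,
        "orders": orders,
        "dominant": dominant,
        "dominant_margin_orders": min(
            orders[dominant] - int(math.floor(math.log10(v))) for v in others
        ),
    }
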