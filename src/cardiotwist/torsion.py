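"""LV torsion and peak torsion rate from basal/apical rotation curves.

Torsion combines the basal-apical rotation difference with ventricular
geometry:

    T(tau) = (BR(tau) - AR(tau)) * (R_apex + R_base) / (2 D)

where BR/AR are basal and apical rotation in degrees, R_apex/R_base the
endocardial radii and D the base-apex length.  Time is normalized to the
fraction of systole tau in [0, 1], which removes heart rate and allows
comparison across species; the statistic of interest is the peak torsion
rate dT/dtau in degrees per tau, read off a cubic spline resampled at a
step of 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .contours import Contour
from .errors import DomainError
from .harp import RotationCurve

__all__ = [
    "TorsionCurve",
    "TorsionRateResult",
    "compute_torsion",
    "resample_percent_systole",
    "peak_torsion_rate",
    "lv_radius",
]


@dataclass
class TorsionCurve:
    tau: np.ndarray
    torsion_deg: np.ndarray
    r_apex_mm: float
    r_base_mm: float
    d_mm: float
    source: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.torsion_deg = np.asarray(self.torsion_deg, dtype=float)
        if self.tau.shape != self.torsion_deg.shape:
            raise DomainError("tau grid and torsion values must align")
        if np.any(np.diff(self.tau) <= 0):
            raise DomainError("tau grid must be strictly increasing")
        if min(self.r_apex_mm, self.r_base_mm, self.d_mm) <= 0:
            raise DomainError("radii and base-apex length must be positive")
        if abs(self.torsion_deg[0]) > 1e-9:
            raise DomainError("torsion must start at 0")


@dataclass
class TorsionRateResult:
    peak_rate_deg_per_tau: float
    tau_at_peak: float
    interpolation_step: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_at_peak <= 1.0:
            raise DomainError("tau at peak must lie in [0, 1]")


def compute_torsion(
    base: RotationCurve,
    apex: RotationCurve,
    r_apex_mm: float,
    r_base_mm: float,
    d_mm: float,
) -> TorsionCurve:
    """T(tau) = (BR - AR)(R_apex + R_base)/(2 D), degrees, on the shared grid."""
    if min(r_apex_mm, r_base_mm) <= 0 or d_mm <= 0:
        raise DomainError("radii and base-apex length must be positive")
    if base.tau.shape != apex.tau.shape or not np.allclose(base.tau, apex.tau):
        raise DomainError("rotation curves must share a tau grid (resample first)")
    t = (base.rotation_deg - apex.rotation_deg) * (r_apex_mm + r_base_mm) / (2.0 * d_mm)
    return TorsionCurve(
        tau=base.tau.copy(),
        torsion_deg=t,
        r_apex_mm=r_apex_mm,
        r_base_mm=r_base_mm,
        d_mm=d_mm,
        source=f"{base.level}-{apex.level}",
    )


def resample_percent_systole(curve: TorsionCurve, step: float = 0.001) -> TorsionCurve:
    """Cubic spline of T versus percent systole on a uniform grid.

    The spline passes through all support points exactly; the not-a-knot
    boundary condition is used so that polynomial curves (through cubics)
    are reproduced exactly, which a natural spline does not do.
    """
    if curve.tau.size < 4:
        raise DomainError("cubic spline interpolation needs at least 4 support points")
    if np.unique(curve.tau).size != curve.tau.size:
        raise DomainError("duplicate tau values")
    spline = CubicSpline(curve.tau, curve.torsion_deg, bc_type="not-a-knot")
    grid = np.arange(0.0, 1.0 + step / 2, step)
    grid = np.clip(grid, curve.tau[0], curve.tau[-1])
    t = spline(grid)
    t = t - t[0]
    return TorsionCurve(
        tau=np.arange(0.0, 1.0 + step / 2, step),
        torsion_deg=t,
        r_apex_mm=curve.r_apex_mm,
        r_base_mm=curve.r_base_mm,
        d_mm=curve.d_mm,
        source=curve.source,
    )


def peak_torsion_rate(curve: TorsionCurve, mode: str = "max_abs") -> TorsionRateResult:
    """Peak torsion rate dT/dtau (degrees per tau) on the resampled grid.

    The derivative is the analytic derivative of the cubic spline through
    the (uniform-grid) curve.  ``mode="max_abs"`` (default) returns
    the signed rate at the tau of maximum |dT/dtau|, matching the
    maximum-absolute-value convention used for strain peaks;
    ``mode="signed"`` returns the maximum signed rate.  Ties resolve to the
    smallest tau.
    """
    steps = np.diff(curve.tau)
    if steps.size < 3 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise DomainError("peak torsion rate requires a uniformly resampled curve")
    spline = CubicSpline(curve.tau, curve.torsion_deg, bc_type="not-a-knot")
    rate = spline.derivative()(curve.tau)
    if mode == "max_abs":
        idx = int(np.argmax(np.abs(rate)))
    elif mode == "signed":
        idx = int(np.argmax(rate))
    else:
        raise DomainError(f"unknown peak mode {mode!r}")
    return TorsionRateResult(
        peak_rate_deg_per_tau=float(rate[idx]),
        tau_at_peak=float(curve.tau[idx]),
        interpolation_step=float(steps[0]),
    )


def secant_torsion_rate(curve: TorsionCurve) -> float:
    """Net change in torsion over one systolic cycle, degrees per tau.

    Exposed alongside the derivative maximum; the derivative maximum is
    the primary statistic.
    """
    span = curve.tau[-1] - curve.tau[0]
    if span <= 0:
        raise DomainError("degenerate tau span")
    return float((curve.torsion_deg[-1] - curve.torsion_deg[0]) / span)


def lv_radius(contour: Contour, level: Optional[str] = None) -> float:
    """LV radius: half the inferior-to-anterior endocardial chord length (mm)."""
    if contour.anterior_index is None or contour.inferior_index is None:
        raise DomainError("contour lacks anterior/inferior orientation labels")
    a = contour.points[contour.anterior_index]
    b = contour.points[contour.inferior_index]
    return float(np.linalg.norm(a - b) / 2.0)
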