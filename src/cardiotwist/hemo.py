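"""Right-ventricular pressure-waveform analysis.

Implements the single-beat estimate of maximum isovolumic ("theoretical")
pressure Pmax by fitting a sinusoid to the isovolumic contraction and
relaxation limbs of one cardiac cycle, and the derived coupling indices:

* end-systolic elastance   Ees = (Pmax - Pes) / SV   [mmHg/mL]
* arterial elastance       Ea  = Pes / SV            [mmHg/mL]
* arterial compliance      C   = SV / PP             [mL/mmHg]
* pulmonary vascular resistance PVR = (mPAP - PCWP) / CO  [Wood units]
* Laplace wall stress      WS  = P * r / h           [mmHg]

Stroke volume is always an explicit input (it comes from imaging or Fick,
never from the pressure trace itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.signal import savgol_filter

from .errors import DomainError, EstimationError

__all__ = [
    "PressureWaveform",
    "Landmarks",
    "HemoResult",
    "detect_landmarks",
    "estimate_pmax",
    "ees",
    "ea",
    "compliance",
    "pvr",
    "wall_stress",
    "analyze_waveform",
]


@dataclass
class Landmarks:
    """Sample indices of the cycle landmarks within one beat."""

    end_diastole: int
    ejection_onset: int
    end_systole: int

    def validate(self) -> None:
        if not self.end_diastole < self.ejection_onset < self.end_systole:
            raise DomainError(
                "landmarks out of order: require ED < ejection onset < ES "
                f"(got {self.end_diastole}, {self.ejection_onset}, {self.end_systole})"
            )


@dataclass
class PressureWaveform:
    """One uniformly sampled ventricular pressure cycle.

    Parameters
    ----------
    pressure:
        Pressure samples in mmHg covering one cardiac cycle.
    dt:
        Sampling interval in seconds.
    landmarks:
        Optional cycle landmarks (stored by the simulator; recomputable
        with :func:`detect_landmarks`).
    truth:
        Optional ground-truth block attached by the simulator
        (keys ``pmax``, ``pes``, ``sv``, ``ees``, ``pp`` ...).
    """

    pressure: np.ndarray
    dt: float
    landmarks: Optional[Landmarks] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.pressure.ndim != 1 or self.pressure.size < 20:
            raise DomainError("waveform needs >= 20 samples in one cycle")
        if self.dt <= 0:
            raise DomainError("sampling interval must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.pressure.size) * self.dt


@dataclass
class HemoResult:
    """Derived hemodynamic indices for one subject."""

    pmax_mmhg: float
    pes_mmhg: float
    sv_ml: float
    pp_mmhg: float
    ees_mmhg_per_ml: float
    ea_mmhg_per_ml: float
    compliance_ml_per_mmhg: float
    pvr_wood: Optional[float] = None
    wall_stress_mmhg: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _noise_sigma(p: np.ndarray) -> float:
    """Noise level from the MAD of second differences (signal curvature is small)."""
    d2 = np.diff(p, 2)
    return float(np.median(np.abs(d2 - np.median(d2))) * 1.4826 / np.sqrt(6.0))


def _smoothed(p: np.ndarray) -> np.ndarray:
    """Savitzky-Golay smoothing for landmark detection, only when noise is present."""
    if _noise_sigma(p) <= 2e-3 * np.ptp(p):
        return p
    window = max(5, (p.size // 15) | 1)
    if window >= p.size:
        window = (p.size - 1) | 1
    return savgol_filter(p, window_length=window, polyorder=3)


def detect_landmarks(waveform: PressureWaveform) -> Landmarks:
    """Locate end-diastole, ejection onset, and end systole in one cycle.

    Ejection onset is taken at maximum dP/dt, end systole at minimum dP/dt
    (steepest fall), and end-diastole at the last pressure minimum preceding
    the systolic upstroke.
    """
    p = waveform.pressure
    if np.ptp(p) < 1e-9:
        raise DomainError("flat pressure signal: no cycle landmarks")
    if _noise_sigma(p) <= 2e-3 * np.ptp(p):
        ps = p
        dpdt = np.gradient(ps, waveform.dt)
    else:
        # noisy trace: a wide Savitzky-Golay derivative keeps the steepest
        # isovolumic fall distinguishable from the ejection-phase descent
        window = max(7, (p.size // 8) | 1)
        if window >= p.size:
            window = (p.size - 1) | 1
        ps = savgol_filter(p, window_length=window, polyorder=3)
        dpdt = savgol_filter(p, window_length=window, polyorder=3, deriv=1, delta=waveform.dt)
    # gate the slope-extremum search to the lower pressure range: the
    # isovolumic limbs live below end-systolic pressure, while the ejection
    # phase (whose descent can be nearly as steep) lives near the maximum
    gate = ps <= ps.min() + 0.6 * np.ptp(ps)
    low = np.where(gate, dpdt, 0.0)
    onset = int(np.argmax(low))
    es = int(np.argmin(low))
    if not onset < es:
        raise DomainError("could not order ejection onset before end systole")
    pre = ps[: onset + 1]
    tol = 0.02 * np.ptp(ps)
    ed_candidates = np.flatnonzero(pre <= pre.min() + tol)
    ed = int(ed_candidates[-1])
    if ed >= onset:
        ed = max(0, onset - 1)
    lm = Landmarks(end_diastole=ed, ejection_onset=onset, end_systole=es)
    lm.validate()
    return lm


def _isovolumic_segments(
    waveform: PressureWaveform, landmarks: Landmarks, trim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays for the contraction and relaxation isovolumic limbs.

    One sample (configurable) is trimmed at each landmark to avoid
    valve-transition samples.
    """
    p = _smoothed(waveform.pressure)
    lo_c = landmarks.end_diastole + trim
    hi_c = landmarks.ejection_onset - trim
    seg_c = np.arange(lo_c, hi_c + 1)

    after = p[landmarks.end_systole :]
    tol = 0.02 * np.ptp(p)
    rel_end = landmarks.end_systole + int(np.flatnonzero(after <= after.min() + tol)[0])
    lo_r = landmarks.end_systole + trim
    hi_r = rel_end - trim
    seg_r = np.arange(lo_r, hi_r + 1)
    if seg_c.size < 4 or seg_r.size < 4:
        raise EstimationError(
            "isovolumic segments too short for the sinusoid fit "
            f"(contraction {seg_c.size}, relaxation {seg_r.size} samples); "
            "increase the sampling rate"
        )
    return seg_c, seg_r


def _fit_sinusoid(t: np.ndarray, p: np.ndarray, omega0: float) -> np.ndarray:
    """Least-squares fit of a + c1*sin(w t) + c2*cos(w t); returns (a, c1, c2, w).

    Nonlinear only in w; the linear coefficients at the initial w seed the
    Levenberg-Marquardt solve (analytic Jacobian, 200 iterations max).
    """
    basis = np.column_stack([np.ones_like(t), np.sin(omega0 * t), np.cos(omega0 * t)])
    coef0, *_ = np.linalg.lstsq(basis, p, rcond=None)

    def residuals(params: np.ndarray) -> np.ndarray:
        a, c1, c2, w = params
        return a + c1 * np.sin(w * t) + c2 * np.cos(w * t) - p

    def jacobian(params: np.ndarray) -> np.ndarray:
        _, c1, c2, w = params
        s, c = np.sin(w * t), np.cos(w * t)
        return np.column_stack([np.ones_like(t), s, c, (c1 * c - c2 * s) * t])

    x0 = np.array([coef0[0], coef0[1], coef0[2], omega0])
    sol = least_squares(
        residuals, x0, jac=jacobian, method="lm", max_nfev=200 * 4, xtol=1e-10, ftol=1e-10
    )
    if not sol.success:
        raise EstimationError(f"sinusoid fit did not converge: {sol.message}")
    return sol.x


def _sinusoid_eval(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, c1, c2, w = params
    return a + c1 * np.sin(w * t) + c2 * np.cos(w * t)


def _refit_with_inliers(
    t: np.ndarray,
    p: np.ndarray,
    seed_idx: np.ndarray,
    candidate_idx: np.ndarray,
    omega0: float,
) -> tuple[float, float, np.ndarray]:
    """Sinusoid fit seeded on ``seed_idx``, re-selecting inliers from a wider
    candidate window (discrete landmarks can be off by a few samples on
    noisy traces; samples off the isovolumic sinusoid are rejected by
    residual)."""
    params = _fit_sinusoid(t[seed_idx], p[seed_idx], omega0)
    idx = seed_idx
    for _ in range(2):
        res_seed = p[idx] - _sinusoid_eval(params, t[idx])
        sigma = float(np.median(np.abs(res_seed - np.median(res_seed))) * 1.4826)
        thr = max(3.0 * sigma, 1e-3 * np.ptp(p))
        res_all = p[candidate_idx] - _sinusoid_eval(params, t[candidate_idx])
        inliers = candidate_idx[np.abs(res_all) < thr]
        if inliers.size < max(8, seed_idx.size // 2):
            break
        idx = inliers
        params = _fit_sinusoid(t[idx], p[idx], params[3])
    a, c1, c2, _ = params
    return float(a), float(np.hypot(c1, c2)), idx


def _crossing_anchored_fit(waveform: PressureWaveform) -> tuple[float, float]:
    """Single-beat sinusoid fit for noisy traces, anchored on the baseline
    crossings.

    The isovolumic limbs start/end where the pressure leaves/returns to the
    diastolic baseline; those crossings are steep and therefore precisely
    localizable under noise, unlike the dP/dt extrema.  A single scalar
    ``u = (a - L)/b`` (the crossing level in units of the sinusoid) then
    determines both the sinusoid frequency, via
    ``omega (t2 - t1) = pi + 2 asin(u)``, and the angular extent of each
    limb, so the self-consistent ``u`` is found by a bracketed root solve
    and the amplitude follows from a linear fit at the implied frequency.
    """
    p, t, dt = waveform.pressure, waveform.time, waveform.dt
    n = p.size
    sigma = max(_noise_sigma(p), 1e-9)
    ps = savgol_filter(p, min(7, (n - 1) | 1), 3)
    b0 = np.percentile(ps, 10)
    flat = ps <= b0 + 2 * sigma
    base = float(np.median(p[flat])) if flat.any() else float(ps.min())
    imax = int(np.argmax(ps))
    level = base + max(4 * sigma, 0.02 * np.ptp(ps))
    before = np.flatnonzero(ps[:imax] <= level)
    after_rel = np.flatnonzero(ps[imax:] <= level)
    if before.size == 0 or after_rel.size == 0:
        raise EstimationError("no baseline crossings: cannot anchor the sinusoid fit")
    i_ed = int(before[-1])
    i_end = imax + int(after_rel[0])

    def cross_time(i0: int, i1: int) -> float:
        y0, y1 = ps[i0], ps[i1]
        f = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
        return float(t[i0] + f * (t[i1] - t[i0]))

    t1 = cross_time(i_ed, min(i_ed + 1, n - 1))
    t2 = cross_time(i_end - 1, i_end)
    span = t2 - t1
    if span <= 8 * dt:
        raise EstimationError("isovolumic span too short for the sinusoid fit")

    def segments(u: float, frac: float = 0.9) -> tuple[np.ndarray, float]:
        gam = np.arcsin(u)
        omega = (np.pi + 2 * gam) / span
        c_hi = t1 + frac * gam / omega
        r_lo = t2 - frac * gam / omega
        idx = np.flatnonzero(((t > t1) & (t <= c_hi)) | ((t >= r_lo) & (t < t2)))
        return idx, omega

    def lin_fit(idx: np.ndarray, omega: float) -> tuple[float, float]:
        basis = np.column_stack([np.ones(idx.size), np.sin(omega * t[idx]), np.cos(omega * t[idx])])
        coef, *_ = np.linalg.lstsq(basis, p[idx], rcond=None)
        return float(coef[0]), float(np.hypot(coef[1], coef[2]))

    def consistency(u: float) -> float:
        idx, omega = segments(u)
        if idx.size < 6:
            return 1.0 - u
        a, amp = lin_fit(idx, omega)
        u_implied = np.clip((a - level) / max(amp, 1e-9), -0.999, 0.999)
        return float(u_implied - u)

    lo, hi = 0.15, 0.97
    if consistency(lo) * consistency(hi) < 0:
        u = float(brentq(consistency, lo, hi, xtol=1e-6))
    else:
        grid = np.linspace(lo, hi, 80)
        u = float(grid[int(np.argmin([abs(consistency(x)) for x in grid]))])
    idx, omega = segments(u, frac=0.97)
    if idx.size < 6:
        raise EstimationError("too few isovolumic samples for the sinusoid fit")
    return lin_fit(idx, omega)


def _single_beat_fit(
    waveform: PressureWaveform,
    landmarks: Landmarks,
    trim: int = 1,
    mode: str = "joint",
) -> tuple[float, float]:
    """Fit the isovolumic sinusoid; returns (mean level a, amplitude b).

    Clean traces use the landmark-delimited segments with a full nonlinear
    fit (exact on noiseless cycles); noisy traces switch to the
    crossing-anchored fit, whose segmentation is robust to derivative
    noise.
    """
    p = waveform.pressure
    if _noise_sigma(p) > 2e-3 * np.ptp(p):
        return _crossing_anchored_fit(waveform)
    seg_c, seg_r = _isovolumic_segments(waveform, landmarks, trim)
    t, p = waveform.time, waveform.pressure
    span = t[landmarks.end_systole] - t[landmarks.ejection_onset]
    omega0 = np.pi / max(span, waveform.dt)
    n = p.size
    cand_c = np.arange(max(0, seg_c[0] - 2), min(n - 1, seg_c[-1] + 3) + 1)
    cand_r = np.arange(max(0, seg_r[0] - 3), min(n - 1, seg_r[-1] + 2) + 1)
    if mode == "joint":
        a, b, _ = _refit_with_inliers(
            t, p, np.concatenate([seg_c, seg_r]), np.concatenate([cand_c, cand_r]), omega0
        )
    elif mode == "per-segment":
        fits = [
            _refit_with_inliers(t, p, seg, cand, omega0)
            for seg, cand in ((seg_c, cand_c), (seg_r, cand_r))
        ]
        a = float(np.mean([f[0] for f in fits]))
        b = float(np.mean([f[1] for f in fits]))
    else:
        raise DomainError(f"unknown fit mode {mode!r}")
    return a, b


def estimate_pmax(
    waveform: PressureWaveform,
    landmarks: Optional[Landmarks] = None,
    *,
    trim: int = 1,
    mode: str = "joint",
) -> float:
    """Single-beat maximum theoretical pressure (mmHg).

    Fits ``P(t) = a + b sin(wt + phi)`` to the isovolumic contraction and
    relaxation segments and returns the sinusoid peak ``a + b``.  ``mode``
    is ``"joint"`` (one fit to both segments, default) or ``"per-segment"``
    (independent fits averaged, for sensitivity analysis).

    Raises
    ------
    EstimationError
        If the fit fails or the fitted peak falls below the recorded
        maximum pressure of an ejecting beat.
    """
    if landmarks is None:
        landmarks = detect_landmarks(waveform)
    a, b = _single_beat_fit(waveform, landmarks, trim, mode)
    pmax = a + b
    _check_pmax_admissible(pmax, waveform)
    return float(pmax)


def _check_pmax_admissible(pmax: float, waveform: PressureWaveform) -> None:
    """An ejecting beat's theoretical peak cannot fall below the recorded
    maximum (compared against the noise-free envelope, with noise slack)."""
    p = waveform.pressure
    sigma = _noise_sigma(p)
    recorded = float(_smoothed(p).max()) if sigma > 2e-3 * np.ptp(p) else float(p.max())
    if pmax < recorded * 0.999 - 3.0 * sigma:
        raise EstimationError(
            f"fitted Pmax {pmax:.2f} mmHg below recorded maximum {recorded:.2f} mmHg; "
            "isovolumic segments may be misidentified"
        )


def ees(pmax: float, pes: float, sv: float) -> float:
    """End-systolic elastance (Pmax - Pes)/SV in mmHg/mL."""
    if sv <= 0:
        raise DomainError("stroke volume must be positive")
    if pmax < pes:
        raise DomainError("Pmax must not be below Pes")
    return (pmax - pes) / sv


def ea(pes: float, sv: float) -> float:
    """Arterial elastance Pes/SV in mmHg/mL."""
    if sv <= 0:
        raise DomainError("stroke volume must be positive")
    return pes / sv


def compliance(sv: float, pp: float) -> float:
    """Arterial compliance SV/PP in mL/mmHg."""
    if pp <= 0:
        raise DomainError("pulse pressure must be positive")
    return sv / pp


def pvr(mpap: float, pcwp: float, co: float) -> float:
    """Pulmonary vascular resistance (mPAP - PCWP)/CO in Wood units.

    mPAP and PCWP in mmHg, CO in L/min.
    """
    if co <= 0:
        raise DomainError("cardiac output must be positive")
    if mpap < pcwp:
        raise DomainError("mPAP must not be below PCWP")
    return (mpap - pcwp) / co


def wall_stress(p: float, r: float, h: float) -> float:
    """Thin-wall Laplace stress P*r/h (same length units for r and h)."""
    if h <= 0:
        raise DomainError("wall thickness must be positive")
    return p * r / h


def analyze_waveform(
    waveform: PressureWaveform,
    sv_ml: float,
    *,
    mpap: Optional[float] = None,
    pcwp: Optional[float] = None,
    co_l_min: Optional[float] = None,
    trim: int = 1,
    mode: str = "joint",
) -> HemoResult:
    """Full single-beat analysis of one pressure cycle.

    Detects landmarks, extrapolates Pmax, and assembles elastance,
    arterial elastance, compliance and (when catheterization values are
    supplied) PVR into a :class:`HemoResult`.
    """
    lm = detect_landmarks(waveform)
    pp = float(waveform.pressure.max() - waveform.pressure.min())
    a, b = _single_beat_fit(waveform, lm, trim, mode)
    pmax = a + b
    _check_pmax_admissible(pmax, waveform)
    # Pressure at the steepest fall of the isovolumic sinusoid equals its
    # mean level, so the fitted `a` is a sub-sample, noise-averaged Pes.
    pes = float(a)
    result = HemoResult(
        pmax_mmhg=pmax,
        pes_mmhg=pes,
        sv_ml=sv_ml,
        pp_mmhg=pp,
        ees_mmhg_per_ml=ees(pmax, pes, sv_ml),
        ea_mmhg_per_ml=ea(pes, sv_ml),
        compliance_ml_per_mmhg=compliance(sv_ml, pp),
    )
    if mpap is not None and pcwp is not None and co_l_min is not None:
        result.pvr_wood = pvr(mpap, pcwp, co_l_min)
    return result
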