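"""Feature-tracking global strain from cine sequences.

Contour points traced at end-diastole are propagated frame to frame by
maximizing normalized cross-correlation of a square template within a
bounded search window (with parabolic sub-pixel refinement), followed by
an along-contour moving average of the point displacements.  Global
engineering strains are then:

* circumferential: percent change of the mid-wall (mean of endo/epi)
  polygon perimeter, averaged over short-axis slices (negative =
  shortening);
* radial: percent change of the mean endo-to-epi distance (positive =
  thickening);
* longitudinal: percent change of the long-axis endocardial arc length
  (negative = shortening).

Peaks are the signed value at the frame of maximum absolute strain (the
max-absolute convention); analyses are repeated with jittered starting
contours and averaged, emulating the triplicate protocol of clinical
feature-tracking reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import match_template

from .contours import SA_LEVELS, Contour, ContourSet
from .errors import DomainError, TrackingQualityError
from .phantom import CineSequence

__all__ = [
    "StrainCurveSet",
    "StrainPeaks",
    "track_contours",
    "circumferential_strain",
    "radial_strain",
    "longitudinal_strain",
    "peak_strain",
    "average_repeats",
    "strain_curves_from_tracked",
]


@dataclass
class StrainCurveSet:
    """Per-ventricle, per-direction global strain (%) and displacement (mm) vs frame."""

    strain: Dict[str, np.ndarray] = field(default_factory=dict)
    displacement: Dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for name, curve in self.strain.items():
            if curve.size == 0:
                raise DomainError(f"empty strain curve {name!r}")
            if abs(curve[0]) > 1e-9:
                raise DomainError(f"strain curve {name!r} must start at 0")


@dataclass
class StrainPeaks:
    """Signed peaks (%) by the maximum-absolute-value rule, plus repeat count."""

    peaks: Dict[str, float]
    peak_frames: Dict[str, int]
    n_repeats: int = 1


# ---------------------------------------------------------------------------
# tracking


def _subpixel_peak(ncc: np.ndarray, iy: int, ix: int) -> Tuple[float, float]:
    """Parabolic refinement of an integer correlation peak, one axis at a time."""

    def refine(vals: np.ndarray, i: int) -> float:
        if i <= 0 or i >= vals.size - 1:
            return 0.0
        denom = vals[i - 1] - 2.0 * vals[i] + vals[i + 1]
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (vals[i - 1] - vals[i + 1]) / denom, -0.5, 0.5))

    return refine(ncc[:, ix], iy), refine(ncc[iy, :], ix)


def _lk_refine(
    tmpl: np.ndarray,
    img1: np.ndarray,
    gy1: np.ndarray,
    gx1: np.ndarray,
    cy: int,
    cx: int,
    half: int,
    iters: int = 5,
) -> Tuple[float, float]:
    """Sub-pixel residual displacement of ``tmpl`` within ``img1`` around (cy, cx)."""
    yy, xx = np.mgrid[cy - half : cy + half + 1, cx - half : cx + half + 1].astype(float)
    d = np.zeros(2)  # (dy, dx)
    for _ in range(iters):
        coords = np.stack([yy + d[0], xx + d[1]])
        patch = map_coordinates(img1, coords, order=1)
        gy = map_coordinates(gy1, coords, order=1)
        gx = map_coordinates(gx1, coords, order=1)
        err = (tmpl - patch).ravel()
        A = np.stack([gy.ravel(), gx.ravel()], axis=1)
        dd, *_ = np.linalg.lstsq(A, err, rcond=None)
        d += dd
        if np.abs(dd).max() < 1e-4:
            break
    return float(d[0]), float(d[1])


def _smooth_along_contour(disp: np.ndarray, window: int, closed: bool) -> np.ndarray:
    if window <= 1:
        return disp
    kernel = np.ones(window) / window
    out = np.empty_like(disp)
    for c in range(disp.shape[1]):
        if closed:
            padded = np.concatenate([disp[-(window // 2):, c], disp[:, c], disp[: window // 2, c]])
            out[:, c] = np.convolve(padded, kernel, mode="valid")[: disp.shape[0]]
        else:
            padded = np.pad(disp[:, c], window // 2, mode="edge")
            out[:, c] = np.convolve(padded, kernel, mode="valid")[: disp.shape[0]]
    return out


def _track_points(
    frames: np.ndarray,
    points_px: np.ndarray,
    *,
    closed: bool,
    template: int,
    search: int,
    smooth_window: int,
    corr_floor: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Propagate one contour through all frames; returns (T, N, 2) px and min-corr per frame."""
    n_frames = frames.shape[0]
    half = template // 2
    tracked = np.empty((n_frames, len(points_px), 2))
    tracked[0] = points_px
    min_corr = np.ones(n_frames)
    pad = half + search
    for f in range(n_frames - 1):
        img0 = np.pad(frames[f], pad, mode="edge")
        img1 = np.pad(frames[f + 1], pad, mode="edge")
        gy1, gx1 = np.gradient(img1)
        disp = np.zeros_like(tracked[f])
        corrs = np.empty(len(points_px))
        for j, (px, py) in enumerate(tracked[f]):
            cx, cy = int(round(px)) + pad, int(round(py)) + pad
            tmpl = img0[cy - half : cy + half + 1, cx - half : cx + half + 1]
            region = img1[cy - half - search : cy + half + search + 1,
                          cx - half - search : cx + half + search + 1]
            ncc = match_template(region, tmpl)
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            corrs[j] = ncc[iy, ix]
            # sub-pixel refinement: a few Lucas-Kanade steps around the
            # integer correlation peak (a parabolic fit of the correlation
            # surface pixel-locks at the sub-pixel motions typical between
            # cine frames)
            dy, dx = _lk_refine(
                tmpl, img1, gy1, gx1, cy + (iy - search), cx + (ix - search), half
            )
            if abs(dy) > 1.5 or abs(dx) > 1.5:
                dy, dx = _subpixel_peak(ncc, iy, ix)
            disp[j] = (ix - search + dx, iy - search + dy)
        disp = _smooth_along_contour(disp, smooth_window, closed)
        tracked[f + 1] = tracked[f] + disp
        min_corr[f + 1] = corrs.min()
        if np.mean(corrs < corr_floor) > 0.2:
            raise TrackingQualityError(
                f"correlation below {corr_floor} for more than 20% of points at frame {f + 1}"
            )
    return tracked, min_corr


def track_contours(
    cine: CineSequence,
    init: ContourSet,
    *,
    template_px: int = 11,
    search_px: int = 3,
    smooth_window: int = 3,
    corr_floor: float = 0.3,
    jitter_px: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[ContourSet]:
    """Propagate all frame-0 contours through a cine sequence.

    Returns one :class:`ContourSet` per frame (frame 0 is the init set,
    optionally jittered by ``jitter_px`` of Gaussian noise on each starting
    point, which is how repeated reads are emulated).  Contours and images
    must belong to the same view (``cine.view``).
    """
    ps = cine.pixel_spacing_mm
    ny, nx = cine.frames.shape[1:]
    if rng is None:
        rng = np.random.default_rng()

    def to_px(points_mm: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [points_mm[:, 0] / ps + (nx - 1) / 2.0, points_mm[:, 1] / ps + (ny - 1) / 2.0]
        )

    def to_mm(points_px: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [(points_px[:, 0] - (nx - 1) / 2.0) * ps, (points_px[:, 1] - (ny - 1) / 2.0) * ps]
        )

    if cine.view == "long_axis":
        items = [(("la", name), c) for name, c in init.la.items()]
    else:
        items = [(key, c) for key, c in init.sa.items() if key[0] == cine.view]
    if not items:
        raise DomainError(f"init contours do not cover view {cine.view!r}")

    out = [
        ContourSet(
            frame=f,
            rv_insertion_indices=init.rv_insertion_indices,
            rv_freewall_points=init.rv_freewall_points,
        )
        for f in range(cine.frames.shape[0])
    ]
    for key, contour in items:
        pts = to_px(contour.points)
        if jitter_px > 0:
            pts = pts + rng.normal(0.0, jitter_px, size=pts.shape)
        tracked, _ = _track_points(
            cine.frames,
            pts,
            closed=contour.closed,
            template=template_px,
            search=search_px,
            smooth_window=smooth_window,
            corr_floor=corr_floor,
        )
        for f in range(cine.frames.shape[0]):
            c = Contour(
                to_mm(tracked[f]),
                closed=contour.closed,
                anterior_index=contour.anterior_index,
                inferior_index=contour.inferior_index,
            )
            if key[0] == "la":
                out[f].la[key[1]] = c
            else:
                out[f].sa[key] = c
    return out


# ---------------------------------------------------------------------------
# strain measures


def _pct_change(values: np.ndarray) -> np.ndarray:
    ref = values[0]
    if ref <= 0:
        raise DomainError("degenerate (zero-length) reference contour")
    return 100.0 * (values - ref) / ref


def circumferential_strain(
    tracked: Sequence[ContourSet], ventricle: str = "lv", levels: Sequence[str] = SA_LEVELS
) -> np.ndarray:
    """Global circumferential strain (%): mid-wall perimeter change, slice-averaged."""
    per_level = []
    for level in levels:
        if (level, f"{ventricle}_endo") not in tracked[0].sa:
            continue
        vals = []
        for cs in tracked:
            endo = cs.sa[(level, f"{ventricle}_endo")].points
            epi = cs.sa[(level, f"{ventricle}_epi")].points
            mid = 0.5 * (endo + epi)
            closed = np.vstack([mid, mid[:1]])
            vals.append(float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))))
        per_level.append(_pct_change(np.asarray(vals)))
    if not per_level:
        raise DomainError(f"no {ventricle} contours at the requested levels")
    return np.mean(per_level, axis=0)


def radial_strain(
    tracked: Sequence[ContourSet], ventricle: str = "lv", levels: Sequence[str] = SA_LEVELS
) -> np.ndarray:
    """Global radial strain (%): mean endo-to-epi wall thickness change, slice-averaged.

    Endo and epi contours are sampled at matching positions, so the wall
    thickness is the mean point-wise distance; for the RV only the
    free-wall segment enters (the septal points are shared with the LV
    epicardium and have zero separation by construction).
    """
    per_level = []
    for level in levels:
        if (level, f"{ventricle}_endo") not in tracked[0].sa:
            continue
        vals = []
        for cs in tracked:
            endo = cs.sa[(level, f"{ventricle}_endo")].points
            epi = cs.sa[(level, f"{ventricle}_epi")].points
            if ventricle == "rv" and cs.rv_freewall_points:
                endo = endo[-cs.rv_freewall_points :]
                epi = epi[-cs.rv_freewall_points :]
            d = np.linalg.norm(epi - endo, axis=1)
            if ventricle == "lv":
                center = 0.5 * (endo.mean(axis=0) + epi.mean(axis=0))
                signed = np.linalg.norm(epi - center, axis=1) - np.linalg.norm(endo - center, axis=1)
                if np.any(signed <= 0):
                    raise DomainError("endo/epi contours cross")
            vals.append(float(d.mean()))
        per_level.append(_pct_change(np.asarray(vals)))
    if not per_level:
        raise DomainError(f"no {ventricle} contours at the requested levels")
    return np.mean(per_level, axis=0)


def longitudinal_strain(tracked: Sequence[ContourSet], ventricle: str = "lv") -> np.ndarray:
    """Global longitudinal strain (%): long-axis endocardial arc length change."""
    name = f"{ventricle}_endo"
    if name not in tracked[0].la:
        raise DomainError(f"no long-axis {name} contour")
    vals = [cs.la[name].arc_length() for cs in tracked]
    return _pct_change(np.asarray(vals))


def _mean_displacement(tracked: Sequence[ContourSet], ventricle: str) -> np.ndarray:
    """Mean point displacement magnitude (mm) of all tracked contours vs frame 0."""
    keys_sa = [k for k in tracked[0].sa if k[1].startswith(ventricle)]
    keys_la = [k for k in tracked[0].la if k.startswith(ventricle)]
    out = []
    for cs in tracked:
        d = []
        for k in keys_sa:
            d.append(np.linalg.norm(cs.sa[k].points - tracked[0].sa[k].points, axis=1))
        for k in keys_la:
            d.append(np.linalg.norm(cs.la[k].points - tracked[0].la[k].points, axis=1))
        out.append(float(np.concatenate(d).mean()) if d else 0.0)
    return np.asarray(out)


def strain_curves_from_tracked(
    tracked_sa: Dict[str, Sequence[ContourSet]],
    tracked_la: Sequence[ContourSet],
    ventricles: Sequence[str] = ("lv", "rv"),
) -> StrainCurveSet:
    """Assemble the full strain curve set from per-view tracked contours.

    ``tracked_sa`` maps level -> per-frame contour sets; ``tracked_la`` is
    the long-axis per-frame sequence.
    """
    merged: List[ContourSet] = []
    n_frames = len(tracked_la)
    for f in range(n_frames):
        cs = ContourSet(frame=f)
        for level, seq in tracked_sa.items():
            cs.sa.update(seq[f].sa)
            cs.rv_freewall_points = seq[f].rv_freewall_points
        cs.la.update(tracked_la[f].la)
        merged.append(cs)

    curves = StrainCurveSet()
    for v in ventricles:
        has_sa = any(k[1] == f"{v}_endo" for k in merged[0].sa)
        if has_sa:
            curves.strain[f"{v}_circ"] = circumferential_strain(merged, v)
            curves.strain[f"{v}_radial"] = radial_strain(merged, v)
        if f"{v}_endo" in merged[0].la:
            curves.strain[f"{v}_long"] = longitudinal_strain(merged, v)
        curves.displacement[f"{v}_displacement"] = _mean_displacement(merged, v)
    curves.validate()
    return curves


def peak_strain(curves: StrainCurveSet) -> StrainPeaks:
    """Signed peak per curve at the frame of maximum absolute value.

    Ties resolve to the earliest frame.  The same rule applies to the
    displacement magnitudes.
    """
    peaks: Dict[str, float] = {}
    frames: Dict[str, int] = {}
    for name, curve in {**curves.strain, **curves.displacement}.items():
        if curve.size == 0:
            raise DomainError(f"empty curve {name!r}")
        idx = int(np.argmax(np.abs(curve)))
        peaks[name] = float(curve[idx])
        frames[name] = idx
    return StrainPeaks(peaks=peaks, peak_frames=frames, n_repeats=1)


def average_repeats(repeats: Sequence[StrainPeaks]) -> StrainPeaks:
    """Arithmetic mean of peak values across repeated analyses."""
    if len(repeats) < 1:
        raise DomainError("need at least one repeat")
    keys = set(repeats[0].peaks)
    for r in repeats[1:]:
        if set(r.peaks) != keys:
            raise DomainError("mismatched metric sets across repeats")
    peaks = {k: float(np.mean([r.peaks[k] for r in repeats])) for k in sorted(keys)}
    frames = {k: int(round(np.mean([r.peak_frames[k] for r in repeats]))) for k in sorted(keys)}
    return StrainPeaks(peaks=peaks, peak_frames=frames, n_repeats=sum(r.n_repeats for r in repeats))
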