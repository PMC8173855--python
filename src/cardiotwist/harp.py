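"""Harmonic-phase (HARP) analysis of tagged image sequences.

The phase of a SPAMM tag pattern's first spectral harmonic is a material
property of the tissue: its frame-to-frame change, for two linearly
independent tag directions, yields the in-plane displacement field.  This
module isolates the harmonic with a Gaussian bandpass in the 2D Fourier
domain, solves the per-pixel 2x2 phase-difference system with one Newton
refinement, and averages the angular component of displacement about the
endocardial centroid into per-slice rotation curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion, map_coordinates
from skimage.registration import phase_cross_correlation

from .errors import ConfigurationError, DomainError, QualityError
from .phantom import TagImageSequence

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseImagePair",
    "DisplacementField",
    "RotationCurve",
    "harmonic_phase",
    "harp_displacement",
    "rotation_curve",
    "rotation_from_tagged",
]


@dataclass
class PhaseImagePair:
    """Wrapped phases and harmonic magnitudes of one frame for both tag directions.

    ``wave_vectors`` rows are the two tag wave-vectors in cycles/mm (x, y
    components, image convention x rightward / y downward).
    """

    phases: Tuple[np.ndarray, np.ndarray]
    magnitudes: Tuple[np.ndarray, np.ndarray]
    wave_vectors: np.ndarray
    frame: int
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        k = np.asarray(self.wave_vectors, dtype=float)
        if k.shape != (2, 2) or abs(np.linalg.det(k)) < 1e-12:
            raise ConfigurationError("wave-vectors must form a nonsingular 2x2 matrix")
        self.wave_vectors = k


@dataclass
class DisplacementField:
    """Per-pixel 2D displacement (mm) between consecutive frames.

    ``u[..., 0]`` is the x component, ``u[..., 1]`` the y component,
    evaluated at the pixel positions of the *later* frame (so the material
    point now at x was at x - u in the earlier frame).  ``valid`` flags
    pixels whose motion stayed within the tracking validity limit of half
    a tag period per direction.
    """

    u: np.ndarray
    valid: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.u = np.where(self.valid[..., None], self.u, 0.0)


@dataclass
class RotationCurve:
    """Cumulative in-plane rotation (degrees) of one slice over systole."""

    level: str
    tau: np.ndarray
    rotation_deg: np.ndarray
    centroid_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        if self.tau.shape != self.rotation_deg.shape:
            raise DomainError("tau grid and rotation values must align")
        if abs(self.rotation_deg[0]) > 1e-9:
            raise DomainError("rotation must be anchored at 0 for the first frame")
        if np.any(np.diff(self.tau) <= 0) or self.tau[0] < 0 or self.tau[-1] > 1:
            raise DomainError("tau grid must be strictly increasing within [0, 1]")


def _wrap(phi: np.ndarray) -> np.ndarray:
    return (phi + np.pi) % (2.0 * np.pi) - np.pi


def harmonic_phase(
    image: np.ndarray,
    wave_vector_cyc_mm: Sequence[float],
    pixel_spacing_mm: float,
    bandwidth_frac: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Isolate one tag harmonic; return (wrapped phase, harmonic magnitude).

    A Gaussian bandpass of s.d. ``bandwidth_frac * |k|`` is centered on the
    spectral peak nearest the nominal wave-vector ``k``; the inverse
    transform's argument is the wrapped phase (radians in [-pi, pi)).

    Raises
    ------
    QualityError
        If no harmonic peak is distinguishable from DC (tag contrast ~ 0).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise DomainError("image must be 2D and at least 32x32")
    k = np.asarray(wave_vector_cyc_mm, dtype=float)
    k_mag = float(np.linalg.norm(k))
    if k_mag * pixel_spacing_mm > 1.0 / 3.0:
        raise ConfigurationError("tag period must be at least 3 pixels")

    F = np.fft.fft2(img)
    fy = np.fft.fftfreq(img.shape[0], d=pixel_spacing_mm)
    fx = np.fft.fftfreq(img.shape[1], d=pixel_spacing_mm)
    fxx, fyy = np.meshgrid(fx, fy)

    # locate the first-harmonic peak nearest the nominal wave-vector
    dist = np.hypot(fxx - k[0], fyy - k[1])
    window = dist <= 0.5 * k_mag
    amps = np.abs(F)
    peak_amp = amps[window].max()
    dc_amp = amps[0, 0]
    if peak_amp < 5e-3 * max(dc_amp, 1e-30):
        raise QualityError("no tag harmonic distinguishable from DC (tag contrast ~ 0)")
    flat = np.where(window, amps, -np.inf)
    iy, ix = np.unravel_index(np.argmax(flat), flat.shape)
    k_peak = np.array([fxx[iy, ix], fyy[iy, ix]])

    sigma = bandwidth_frac * k_mag
    G = np.exp(-((fxx - k_peak[0]) ** 2 + (fyy - k_peak[1]) ** 2) / (2.0 * sigma**2))
    # suppress the DC lobe explicitly: a wide bandpass otherwise admits the
    # (static) tissue envelope, whose phasor drags the motion-encoding phase
    G = G * (1.0 - np.exp(-(fxx**2 + fyy**2) / (2.0 * (0.45 * k_mag) ** 2)))
    h = np.fft.ifft2(F * G)
    return np.angle(h).astype(float), np.abs(h).astype(float)


def _resample_phase(phase: np.ndarray, magnitude: np.ndarray, coords_px: np.ndarray) -> np.ndarray:
    """Interpolate a wrapped phase map via its complex representation."""
    z = magnitude * np.exp(1j * phase)
    re = map_coordinates(z.real, coords_px, order=1, mode="nearest")
    im = map_coordinates(z.imag, coords_px, order=1, mode="nearest")
    return np.arctan2(im, re)


def harp_displacement(
    pair_t: PhaseImagePair,
    pair_t1: PhaseImagePair,
    mask: Optional[np.ndarray] = None,
    *,
    refine_iters: int = 0,
    quality_frac: float = 0.1,
) -> DisplacementField:
    """Solve the per-pixel phase-difference system for displacement (mm).

    For each pixel the wrapped phase differences in the two tag directions
    give ``2 pi K d = dphi`` with ``K`` the wave-vector matrix; a Newton
    step resamples the earlier frame's phase at the displaced position and
    re-solves on the residual.  Pixels whose motion jumps tags (exceeds
    half a tag period per direction, detected against a bulk-shift prior
    from phase correlation of the harmonic magnitude images) are flagged
    invalid.
    """
    if pair_t.phases[0].shape != pair_t1.phases[0].shape:
        raise DomainError("frames must share geometry")
    K = pair_t1.wave_vectors
    if abs(np.linalg.det(K)) < 1e-12:
        raise ConfigurationError("singular wave-vector matrix")
    Kinv = np.linalg.inv(K)
    ps = pair_t1.pixel_spacing_mm
    shape = pair_t.phases[0].shape

    dphi = np.stack(
        [_wrap(pair_t1.phases[i] - pair_t.phases[i]) for i in range(2)], axis=-1
    )
    # the harmonic phase labels the REFERENCE coordinate, which moves against
    # the displacement: dphi = -2 pi K d, so d = -K^-1 dphi / (2 pi)
    d = -dphi @ (Kinv.T / (2.0 * np.pi))

    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    for _ in range(max(0, refine_iters)):
        coords = np.stack([yy - d[..., 1] / ps, xx - d[..., 0] / ps])
        resampled = np.stack(
            [
                _resample_phase(pair_t.phases[i], pair_t.magnitudes[i], coords)
                for i in range(2)
            ],
            axis=-1,
        )
        residual = _wrap(np.stack([pair_t1.phases[i] for i in range(2)], axis=-1) - resampled)
        d = d - residual @ (Kinv.T / (2.0 * np.pi))

    # quality mask: harmonic magnitude above a fraction of its in-slice max
    qual = np.ones(shape, dtype=bool)
    for i in range(2):
        m = pair_t1.magnitudes[i]
        qual &= m >= quality_frac * m.max()
    if mask is not None:
        qual &= np.asarray(mask, dtype=bool)

    # tag-jump detection against a bulk-shift prior (aliasing is invisible
    # in a single wrapped phase difference)
    shift_px, *_ = phase_cross_correlation(
        pair_t1.magnitudes[0], pair_t.magnitudes[0], upsample_factor=10
    )
    d_bulk = np.array([shift_px[1], shift_px[0]]) * ps  # (dy, dx) px -> (dx, dy) mm
    jumps = np.rint((d - d_bulk) @ K.T)  # cycles of disagreement per direction
    valid = qual & np.all(jumps == 0, axis=-1)
    return DisplacementField(u=d, valid=valid, pixel_spacing_mm=ps)


def rotation_curve(
    fields: Sequence[DisplacementField],
    centroids_mm: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    tau: Sequence[float],
    level: str = "mid",
) -> RotationCurve:
    """Accumulate per-frame rotation increments into a rotation curve.

    ``fields[i]`` is the displacement from frame i to frame i+1 (evaluated
    on frame i+1 pixels); ``centroids_mm[i]`` is the endocardial centroid
    of frame i (removing bulk translation before angular averaging);
    ``masks[i+1]`` is the myocardial mask on frame i+1.  The increment is
    the mean wrapped change in polar angle about the centroid, in degrees.
    """
    if len(fields) < 1:
        raise DomainError("need at least 2 frames (1 displacement field)")
    increments = [0.0]
    for i, fld in enumerate(fields):
        ny, nx = fld.valid.shape
        ps = fld.pixel_spacing_mm
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        pos = np.stack([(xx - (nx - 1) / 2.0) * ps, (yy - (ny - 1) / 2.0) * ps], axis=-1)
        sel = fld.valid & np.asarray(masks[i + 1], dtype=bool)
        if not np.any(sel):
            raise DomainError(f"empty myocardial mask at frame pair {i}->{i + 1}")
        after = pos[sel] - np.asarray(centroids_mm[i + 1])
        before = pos[sel] - fld.u[sel] - np.asarray(centroids_mm[i])
        dtheta = _wrap(np.arctan2(after[:, 1], after[:, 0]) - np.arctan2(before[:, 1], before[:, 0]))
        increments.append(math.degrees(float(np.mean(dtheta))))
    rot = np.cumsum(increments)
    rot -= rot[0]
    return RotationCurve(level=level, tau=np.asarray(tau, dtype=float), rotation_deg=rot)


def rotation_from_tagged(
    seq: TagImageSequence,
    masks: Sequence[np.ndarray],
    centroids_mm: Sequence[np.ndarray],
    *,
    bandwidth_frac: float = 0.5,
    refine_iters: int = 0,
    mask_erosion_px: int = 1,
) -> RotationCurve:
    """End-to-end rotation recovery for one tagged slice sequence.

    The myocardial masks are eroded by ``mask_erosion_px`` before angular
    averaging (the bandpass kernel bleeds phase across tissue boundaries);
    frames whose harmonic has faded below the quality floor are dropped
    from the curve with a warning.
    """
    if mask_erosion_px > 0:
        masks = [binary_erosion(np.asarray(m, bool), iterations=mask_erosion_px) for m in masks]
    K = seq.wave_vectors
    pairs: List[Optional[PhaseImagePair]] = []
    kept: List[int] = []
    for f in range(seq.frames.shape[0]):
        try:
            ph, mg = zip(
                *(
                    harmonic_phase(seq.frames[f], K[i], seq.pixel_spacing_mm, bandwidth_frac)
                    for i in range(2)
                )
            )
        except QualityError:
            logger.warning("dropping frame %d: tag harmonic below quality floor", f)
            pairs.append(None)
            continue
        pairs.append(
            PhaseImagePair(
                phases=ph, magnitudes=mg, wave_vectors=K, frame=f, pixel_spacing_mm=seq.pixel_spacing_mm
            )
        )
        kept.append(f)
    if len(kept) < 2:
        raise QualityError("fewer than 2 usable tagged frames")
    fields = [
        harp_displacement(pairs[kept[j]], pairs[kept[j + 1]], refine_iters=refine_iters)
        for j in range(len(kept) - 1)
    ]
    return rotation_curve(
        fields,
        [centroids_mm[f] for f in kept],
        [masks[f] for f in kept],
        tau=seq.tau[kept],
        level=seq.level,
    )
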