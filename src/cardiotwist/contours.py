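"""Contour containers shared by the phantom, torsion and strain modules.

Coordinates are in mm, image convention: origin at the center of pixel
(0, 0), x rightward, y downward.  Short-axis contours are ordered by
increasing polar angle about the slice centroid; the anatomical
``anterior`` direction is -y (top of the image) and ``inferior`` is +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import DomainError

SA_LEVELS = ("base", "mid", "apex")


@dataclass
class Contour:
    """A single ordered point list (N, 2) in mm.

    ``closed`` marks ring contours (short axis); long-axis contours are
    open polylines running base -> apex -> base.
    """

    points: np.ndarray
    closed: bool = True
    anterior_index: Optional[int] = None
    inferior_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DomainError("contour points must be an (N, 2) array")
        if len(self.points) < 24:
            raise DomainError("contours need at least 24 points")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def perimeter(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def arc_length(self) -> float:
        """Open polyline length (no closing segment)."""
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class ContourSet:
    """All traced borders for one frame.

    ``sa`` maps (level, name) -> Contour with level in {base, mid, apex}
    and name in {lv_endo, lv_epi, rv_endo, rv_epi}; ``la`` maps name
    (lv_endo, rv_endo) -> long-axis Contour.  When an RV crescent is
    present, the RV endocardial septal segment is point-identical to the
    corresponding LV epicardial arc, and ``rv_insertion_indices`` gives
    the first/last shared indices on the LV epicardium.
    """

    frame: int
    sa: Dict[tuple, Contour] = field(default_factory=dict)
    la: Dict[str, Contour] = field(default_factory=dict)
    rv_insertion_indices: Optional[tuple] = None
    rv_freewall_points: Optional[int] = None

    def lv_mask(self, level: str, shape: tuple, pixel_spacing_mm: float) -> np.ndarray:
        """Boolean myocardial mask between LV endo and epi for one slice."""
        endo = self.sa[(level, "lv_endo")]
        epi = self.sa[(level, "lv_epi")]
        ny, nx = shape
        ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing_mm
        xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing_mm
        xx, yy = np.meshgrid(xs, ys)
        c = epi.centroid
        r = np.hypot(xx - c[0], yy - c[1])
        r_endo = np.linalg.norm(endo.points - endo.centroid, axis=1).mean()
        r_epi = np.linalg.norm(epi.points - epi.centroid, axis=1).mean()
        return (r >= r_endo) & (r <= r_epi)


def circle_contour(
    radius_mm: float,
    n_points: int = 64,
    center: tuple = (0.0, 0.0),
) -> Contour:
    """Angle-ordered circular contour with anterior (-y) and inferior (+y) labels."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius_mm * np.cos(theta), center[1] + radius_mm * np.sin(theta)]
    )
    anterior = int(np.argmin(pts[:, 1]))
    inferior = int(np.argmax(pts[:, 1]))
    return Contour(pts, closed=True, anterior_index=anterior, inferior_index=inferior)
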