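"""File interchange: TIFF stacks with JSON sidecars, contour/waveform/curve files.

Image stacks are multi-page 32-bit float TIFF with a JSON sidecar carrying
pixel spacing (mm), the tau grid, tag geometry and slice level.  Contours
are JSON point lists in mm (image origin at the center of pixel (0,0), x
rightward, y downward).  Waveforms are 2-column CSV (time_s,
pressure_mmHg) plus a JSON landmark block; cohorts and curves are plain
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .contours import Contour, ContourSet
from .harp import RotationCurve
from .hemo import Landmarks, PressureWaveform
from .phantom import CineSequence, TagImageSequence
from .torsion import TorsionCurve

PathLike = Union[str, Path]


def _sidecar(path: PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json") if p.suffix != ".tif" else p.with_suffix(".json")


def write_tagged_sequence(seq: TagImageSequence, path: PathLike) -> None:
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    meta = {
        "kind": "tagged",
        "pixel_spacing_mm": seq.pixel_spacing_mm,
        "tag_spacing_mm": seq.tag_spacing_mm,
        "tag_angle_deg": seq.tag_angle_deg,
        "tau": seq.tau.tolist(),
        "level": seq.level,
        "wave_vectors_cyc_mm": seq.wave_vectors.tolist(),
        **seq.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_tagged_sequence(path: PathLike) -> TagImageSequence:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return TagImageSequence(
        frames=np.asarray(frames, dtype=np.float32),
        pixel_spacing_mm=meta["pixel_spacing_mm"],
        tag_spacing_mm=meta["tag_spacing_mm"],
        tag_angle_deg=meta.get("tag_angle_deg", 0.0),
        tau=np.asarray(meta["tau"], dtype=float),
        level=meta["level"],
        meta={k: v for k, v in meta.items() if k not in {"kind", "pixel_spacing_mm", "tag_spacing_mm", "tag_angle_deg", "tau", "level", "wave_vectors_cyc_mm"}},
    )


def write_cine_sequence(seq: CineSequence, path: PathLike) -> None:
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    meta = {
        "kind": "cine",
        "pixel_spacing_mm": seq.pixel_spacing_mm,
        "tau": seq.tau.tolist(),
        "view": seq.view,
        **seq.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_cine_sequence(path: PathLike) -> CineSequence:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return CineSequence(
        frames=np.asarray(frames, dtype=np.float32),
        pixel_spacing_mm=meta["pixel_spacing_mm"],
        tau=np.asarray(meta["tau"], dtype=float),
        view=meta["view"],
        meta={k: v for k, v in meta.items() if k not in {"kind", "pixel_spacing_mm", "tau", "view"}},
    )


def write_nifti(seq: Union[TagImageSequence, CineSequence], path: PathLike) -> None:
    """Optional NIfTI-1 export for interoperability with imaging viewers."""
    import nibabel as nib

    data = np.moveaxis(seq.frames, 0, -1).astype(np.float32)
    affine = np.diag([seq.pixel_spacing_mm, seq.pixel_spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _contour_to_dict(c: Contour) -> dict:
    return {
        "points_mm": np.asarray(c.points).tolist(),
        "closed": c.closed,
        "anterior_index": c.anterior_index,
        "inferior_index": c.inferior_index,
    }


def _contour_from_dict(d: dict) -> Contour:
    return Contour(
        np.asarray(d["points_mm"], dtype=float),
        closed=d.get("closed", True),
        anterior_index=d.get("anterior_index"),
        inferior_index=d.get("inferior_index"),
    )


def write_contours(cs: ContourSet, path: PathLike) -> None:
    payload = {
        "frame": cs.frame,
        "rv_insertion_indices": list(cs.rv_insertion_indices) if cs.rv_insertion_indices else None,
        "rv_freewall_points": cs.rv_freewall_points,
        "sa": {f"{level}/{name}": _contour_to_dict(c) for (level, name), c in cs.sa.items()},
        "la": {name: _contour_to_dict(c) for name, c in cs.la.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_contours(path: PathLike) -> ContourSet:
    d = json.loads(Path(path).read_text())
    cs = ContourSet(
        frame=d["frame"],
        rv_insertion_indices=tuple(d["rv_insertion_indices"]) if d.get("rv_insertion_indices") else None,
        rv_freewall_points=d.get("rv_freewall_points"),
    )
    for key, cd in d.get("sa", {}).items():
        level, name = key.split("/")
        cs.sa[(level, name)] = _contour_from_dict(cd)
    for name, cd in d.get("la", {}).items():
        cs.la[name] = _contour_from_dict(cd)
    return cs


def write_waveform(w: PressureWaveform, path: PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": w.time, "pressure_mmhg": w.pressure})
    df.to_csv(path, index=False)
    meta = {"dt_s": w.dt, "truth": w.truth}
    if w.landmarks is not None:
        meta["landmarks"] = {
            "end_diastole": w.landmarks.end_diastole,
            "ejection_onset": w.landmarks.ejection_onset,
            "end_systole": w.landmarks.end_systole,
        }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_waveform(path: PathLike) -> PressureWaveform:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar(path)
    landmarks, truth, dt = None, {}, None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        dt = meta.get("dt_s")
        truth = meta.get("truth", {})
        if "landmarks" in meta:
            landmarks = Landmarks(**meta["landmarks"])
    if dt is None:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    return PressureWaveform(pressure=df["pressure_mmhg"].to_numpy(), dt=dt, landmarks=landmarks, truth=truth)


def write_rotation_curve(curve: RotationCurve, path: PathLike) -> None:
    pd.DataFrame({"tau": curve.tau, "rotation_deg": curve.rotation_deg}).to_csv(path, index=False)


def write_torsion_curve(curve: TorsionCurve, path: PathLike) -> None:
    pd.DataFrame({"tau": curve.tau, "torsion_deg": curve.torsion_deg}).to_csv(path, index=False)
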