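"""Harmonic-phase analysis: phase recovery, displacement solving, rotation curves."""

import math

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from cardiotwist.errors import DomainError, QualityError
from cardiotwist.harp import (
    PhaseImagePair,
    _wrap,
    harmonic_phase,
    harp_displacement,
    rotation_curve,
    rotation_from_tagged,
)
from cardiotwist.phantom import make_contours, simulate_tagged_sequence

PS = 0.15
SPACING = 0.7


def _grid_mm(n):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return (xx - c) * PS, (yy - c) * PS


def _pattern(x, y, angle_deg=0.0):
    a = math.radians(angle_deg)
    u = x * math.cos(a) + y * math.sin(a)
    v = -x * math.sin(a) + y * math.cos(a)
    w = 2 * np.pi / SPACING
    return (0.5 + 0.5 * np.cos(w * u)) * (0.5 + 0.5 * np.cos(w * v))


def _pair(img, frame=0):
    k = np.array([[1 / SPACING, 0.0], [0.0, 1 / SPACING]])
    ph, mg = zip(*(harmonic_phase(img, k[i], PS) for i in range(2)))
    return PhaseImagePair(phases=ph, magnitudes=mg, wave_vectors=k, frame=frame, pixel_spacing_mm=PS)


class TestHarmonicPhase:
    def test_pure_cosine_phase_matches_analytic(self):
        x, y = _grid_mm(96)
        img = 0.5 + 0.5 * np.cos(2 * np.pi * x / SPACING)
        k = np.array([1 / SPACING, 0.0])
        phase, _ = harmonic_phase(img, k, PS)
        analytic = _wrap(2 * np.pi * x / SPACING)
        err = np.abs(_wrap(phase - analytic))[4:-4, 4:-4]
        assert err.max() < 0.05

    def test_uniform_image_raises_quality_error(self):
        with pytest.raises(QualityError):
            harmonic_phase(np.full((64, 64), 0.7), np.array([1 / SPACING, 0.0]), PS)

    def test_translated_pattern_phase_difference(self):
        x, y = _grid_mm(96)
        delta = 0.2 * SPACING
        img0 = _pattern(x, y)
        img1 = _pattern(x - delta, y)
        k = np.array([1 / SPACING, 0.0])
        p0, _ = harmonic_phase(img0, k, PS)
        p1, _ = harmonic_phase(img1, k, PS)
        dphi = _wrap(p1 - p0)[8:-8, 8:-8]
        assert np.abs(dphi - (-2 * np.pi * delta / SPACING)).max() < 0.1

    def test_small_image_rejected(self):
        with pytest.raises(DomainError):
            harmonic_phase(np.zeros((16, 16)), np.array([1 / SPACING, 0.0]), PS)


class TestDisplacement:
    def test_identical_frames_give_zero_field(self):
        x, y = _grid_mm(96)
        pair = _pair(_pattern(x, y))
        fld = harp_displacement(pair, pair)
        assert np.abs(fld.u[fld.valid]).max() < 1e-9

    def test_rigid_subpixel_translation_recovered(self):
        x, y = _grid_mm(96)
        delta = 0.5 * SPACING * 0.4
        p0 = _pair(_pattern(x, y))
        p1 = _pair(_pattern(x - delta, y - 0.5 * delta), frame=1)
        fld = harp_displacement(p0, p1)
        inner = np.zeros_like(fld.valid)
        inner[16:-16, 16:-16] = True
        sel = fld.valid & inner
        assert abs(fld.u[sel][:, 0].mean() - delta) / delta < 0.05
        assert abs(fld.u[sel][:, 1].mean() - 0.5 * delta) / (0.5 * delta) < 0.05

    def test_motion_beyond_half_tag_spacing_flagged(self):
        x, y = _grid_mm(96)
        delta = 0.6 * SPACING
        p0 = _pair(_pattern(x, y))
        p1 = _pair(_pattern(x - delta, y), frame=1)
        fld = harp_displacement(p0, p1)
        inner = np.zeros(fld.valid.shape, dtype=bool)
        inner[16:-16, 16:-16] = True
        # aliased motion must be flagged invalid on the bulk of the image
        assert (~fld.valid[inner]).mean() > 0.9

    def test_solver_agrees_with_brute_force_shift_search(self):
        """On 16x16 tiles, the 2x2 solve matches an exhaustive sub-pixel
        search that maximizes phase agreement."""
        x, y = _grid_mm(96)
        delta = (0.12, -0.07)  # mm
        p0 = _pair(_pattern(x, y))
        p1 = _pair(_pattern(x - delta[0], y - delta[1]), frame=1)
        fld = harp_displacement(p0, p1)

        z0 = [m * np.exp(1j * p) for p, m in zip(p0.phases, p0.magnitudes)]

        def mismatch(dx_mm, dy_mm, sl):
            yy, xx = np.mgrid[sl[0], sl[1]].astype(float)
            coords = np.stack([yy - dy_mm / PS, xx - dx_mm / PS])
            total = 0.0
            for i in range(2):
                re = map_coordinates(z0[i].real, coords, order=1)
                im = map_coordinates(z0[i].imag, coords, order=1)
                resampled = np.arctan2(im, re)
                total += np.mean(_wrap(p1.phases[i][sl] - resampled) ** 2)
            return total

        sl = (slice(40, 56), slice(40, 56))  # one 16x16 tile
        grid = np.arange(-0.3, 0.3, 0.005)  # mm, ~0.03 px steps
        best = min(((mismatch(dx, dy, sl), dx, dy) for dx in grid for dy in grid))
        _, bx, by = best
        est = fld.u[sl][fld.valid[sl]].mean(axis=0)
        assert abs(est[0] - bx) < 0.1 * PS
        assert abs(est[1] - by) < 0.1 * PS


class TestRotationCurve:
    def _curves(self, spec, level):
        seq = simulate_tagged_sequence(spec, level, noise_sd=0.0, fade_per_frame=1.0, seed=0)
        masks, cents = [], []
        for f in range(spec.n_frames):
            cs = make_contours(spec, f)
            masks.append(cs.lv_mask(level, spec.image_shape, spec.pixel_spacing_mm))
            cents.append(cs.sa[(level, "lv_endo")].centroid)
        return rotation_from_tagged(seq, masks, cents)

    @pytest.mark.parametrize("rot,tol", [(6.0, 0.05), (15.0, 0.06)])
    def test_prescribed_apical_rotation_recovered(self, rot, tol):
        from cardiotwist.phantom import PhantomSpec

        spec = PhantomSpec.mouse(
            basal_rotation_deg=-rot / 3, apical_rotation_deg=rot,
            circ_shortening_frac=0, radial_thickening_frac=0, long_shortening_frac=0,
        )
        rc = self._curves(spec, "apex")
        assert abs(rc.rotation_deg[-1] - rot) / rot < tol

    def test_radial_thickening_produces_no_spurious_rotation(self):
        from cardiotwist.phantom import PhantomSpec

        spec = PhantomSpec.mouse(
            basal_rotation_deg=0, apical_rotation_deg=0,
            circ_shortening_frac=0, radial_thickening_frac=0.3, long_shortening_frac=0,
        )
        rc = self._curves(spec, "mid")
        assert np.abs(rc.rotation_deg).max() < 0.2

    def test_pure_translation_produces_no_spurious_rotation(self):
        from cardiotwist.phantom import PhantomSpec

        spec = PhantomSpec.mouse(
            basal_rotation_deg=0, apical_rotation_deg=0,
            circ_shortening_frac=0, radial_thickening_frac=0, long_shortening_frac=0,
            translation_mm=(0.3, 0.2),
        )
        rc = self._curves(spec, "mid")
        assert np.abs(rc.rotation_deg).max() < 0.2

    def test_tag_orientation_invariance(self, rotation_only_spec):
        spec = rotation_only_spec
        vals = []
        for ang in (0.0, 45.0):
            seq = simulate_tagged_sequence(spec, "apex", tag_angle_deg=ang,
                                           noise_sd=0.0, fade_per_frame=1.0, seed=0)
            masks, cents = [], []
            for f in range(spec.n_frames):
                cs = make_contours(spec, f)
                masks.append(cs.lv_mask("apex", spec.image_shape, spec.pixel_spacing_mm))
                cents.append(cs.sa[("apex", "lv_endo")].centroid)
            vals.append(rotation_from_tagged(seq, masks, cents).rotation_deg[-1])
        assert abs(vals[0] - vals[1]) / abs(vals[0]) < 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            x, y = _grid_mm(96)
            p0 = _pair(_pattern(x, y))
            fld = harp_displacement(p0, p0)
            rotation_curve([fld], [np.zeros(2)] * 2, [np.zeros_like(fld.valid)] * 2,
                           tau=[0.0, 1.0])
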