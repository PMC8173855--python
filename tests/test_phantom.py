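"""Phantom generator: deformation kinematics, rendering, contours, pressure, cohorts."""

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from cardiotwist.contours import SA_LEVELS
from cardiotwist.errors import ConfigurationError
from cardiotwist.hemo import detect_landmarks
from cardiotwist.phantom import (
    CohortConfig,
    GroupBlock,
    PhantomSpec,
    PressureParams,
    deform,
    make_contours,
    render_cine,
    render_spamm,
    sample_cohort,
    simulate_pressure,
)


class TestDeformation:
    def test_frame_zero_is_identity(self, mouse_spec, rng):
        fld = deform(mouse_spec, 0)
        pts = rng.normal(0.0, 2.0, (200, 2))
        for level in SA_LEVELS:
            assert np.allclose(fld.map_points(pts, level), pts, atol=1e-12)
        assert np.allclose(fld.map_points_la(pts), pts, atol=1e-12)

    def test_forward_inverse_identity(self, mouse_spec, rng):
        fld = deform(mouse_spec, mouse_spec.n_frames - 1)
        pts = rng.normal(0.0, 2.5, (300, 2))
        for level in SA_LEVELS:
            back = fld.unmap_points(fld.map_points(pts, level), level)
            assert np.abs(back - pts).max() < 1e-6
        back = fld.unmap_points_la(fld.map_points_la(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_end_systolic_rotation_at_named_slices(self, rotation_only_spec):
        spec = rotation_only_spec
        fld = deform(spec, spec.n_frames - 1)
        for level, expect in (("base", spec.basal_rotation_deg), ("apex", spec.apical_rotation_deg)):
            p = np.array([[spec.endo_radius_mm[level] + 0.2, 0.0]])
            q = fld.map_points(p, level)
            ang = np.degrees(np.arctan2(q[0, 1], q[0, 0]))
            assert ang == pytest.approx(expect, abs=1e-9)

    def test_midwall_perimeter_scales_with_circumferential_knob(self):
        spec = PhantomSpec.mouse(
            circ_shortening_frac=0.2, radial_thickening_frac=0.0,
            basal_rotation_deg=0.0, apical_rotation_deg=0.0,
        )
        fld = deform(spec, spec.n_frames - 1)
        rm = 0.5 * (spec.endo_radius_mm["mid"] + spec.epi_radius_mm["mid"])
        theta = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        ring = np.column_stack([rm * np.cos(theta), rm * np.sin(theta)])
        mapped = fld.map_points(ring, "mid")
        closed = np.vstack([mapped, mapped[:1]])
        perim = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        assert perim / (2 * np.pi * rm) == pytest.approx(0.8, abs=1e-6)

    def test_wall_thickness_scales_with_radial_knob(self, mouse_spec):
        fld = deform(mouse_spec, mouse_spec.n_frames - 1)
        endo = mouse_spec.endo_radius_mm["mid"]
        epi = mouse_spec.epi_radius_mm["mid"]
        q = fld.map_points(np.array([[endo, 0.0], [epi, 0.0]]), "mid")
        thick = np.linalg.norm(q[1] - q[0])
        expect = (epi - endo) * (1.0 + mouse_spec.radial_thickening_frac)
        assert thick == pytest.approx(expect, rel=1e-9)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec.mouse(endo_radius_mm={"base": -1.0, "mid": 1.9, "apex": 1.5})
        with pytest.raises(ConfigurationError):
            PhantomSpec.mouse(n_frames=2)

    def test_frame_out_of_range(self, mouse_spec):
        with pytest.raises(IndexError):
            deform(mouse_spec, mouse_spec.n_frames)


class TestRendering:
    def test_frame_zero_equals_undeformed_pattern(self, mouse_spec):
        img0 = render_spamm(mouse_spec, deform(mouse_spec, 0), "mid",
                            fade_per_frame=1.0, noise_sd=0.0, psf_sigma_px=0.0)
        # re-render from an explicitly identity field of another frame=0 call
        img0b = render_spamm(mouse_spec, deform(mouse_spec, 0), "mid",
                             fade_per_frame=0.9, noise_sd=0.0, psf_sigma_px=0.0)
        assert np.array_equal(img0, img0b)  # fade^0 == 1

    def test_tag_spacing_below_resolvable_limit_rejected(self, mouse_spec):
        with pytest.raises(ConfigurationError):
            render_spamm(mouse_spec, deform(mouse_spec, 0), "mid",
                         tag_spacing_mm=2.0 * mouse_spec.pixel_spacing_mm)

    def test_rigid_translation_moves_tag_pattern(self):
        spec = PhantomSpec.mouse(
            basal_rotation_deg=0, apical_rotation_deg=0,
            circ_shortening_frac=0, radial_thickening_frac=0, long_shortening_frac=0,
            translation_mm=(2 * 0.15, 0.0),  # 2 px at end systole
        )
        a = render_spamm(spec, deform(spec, 0), "mid", fade_per_frame=1.0,
                         noise_sd=0.0, psf_sigma_px=0.0)
        b = render_spamm(spec, deform(spec, spec.n_frames - 1), "mid", fade_per_frame=1.0,
                         noise_sd=0.0, psf_sigma_px=0.0)
        # cross-correlate rows: maximum at lag 2
        lags = np.arange(-4, 5)
        scores = [np.sum(a[:, 4:-4] * np.roll(b, -lag, axis=1)[:, 4:-4]) for lag in lags]
        assert lags[int(np.argmax(scores))] == 2

    def test_tag_fading_reduces_harmonic_amplitude_geometrically(self, rotation_only_spec):
        from cardiotwist.harp import harmonic_phase

        spec = rotation_only_spec
        k = np.array([1.0 / spec.tag_spacing_mm, 0.0])
        mags = []
        for frame, fade in ((0, 0.9), (5, 0.9)):
            img = render_spamm(spec, deform(spec, 0), "mid", fade_per_frame=fade,
                               noise_sd=0.0, psf_sigma_px=0.0)
            if frame:  # emulate frame index via explicit amplitude
                fld = deform(spec, 0)
                fld.frame = 5
                img = render_spamm(spec, fld, "mid", fade_per_frame=fade,
                                   noise_sd=0.0, psf_sigma_px=0.0)
            _, mag = harmonic_phase(img, k, spec.pixel_spacing_mm)
            cs = make_contours(spec, 0)
            mask = cs.lv_mask("mid", spec.image_shape, spec.pixel_spacing_mm)
            # interior of the wall: the boundary leakage floor is fade-independent
            mask = binary_erosion(mask, iterations=2)
            mags.append(mag[mask].mean())
        assert mags[1] / mags[0] == pytest.approx(0.9**5, rel=0.05)

    def test_cine_threshold_segmentation_recovers_radii(self, mouse_spec):
        img = render_cine(mouse_spec, deform(mouse_spec, 0), "mid",
                          noise_sd=0.0, texture_amp=0.0, psf_sigma_px=0.0)
        ny, nx = img.shape
        ps = mouse_spec.pixel_spacing_mm
        ys = (np.arange(ny) - (ny - 1) / 2) * ps
        xs = (np.arange(nx) - (nx - 1) / 2) * ps
        xx, yy = np.meshgrid(xs, ys)
        r = np.hypot(xx, yy)
        blood = img > 0.8
        # restrict to LV cavity (exclude RV crescent blood)
        lv_blood = blood & (r < mouse_spec.endo_radius_mm["mid"] + 0.5)
        assert abs(r[lv_blood].max() - mouse_spec.endo_radius_mm["mid"]) < ps

    def test_cine_wall_thickness_scales(self, mouse_spec):
        img = render_cine(mouse_spec, deform(mouse_spec, mouse_spec.n_frames - 1), "mid",
                          noise_sd=0.0, texture_amp=0.0, psf_sigma_px=0.0)
        ps = mouse_spec.pixel_spacing_mm
        ny, nx = img.shape
        # radial profile along +y (away from the RV crescent at 180 deg)
        col = img[ny // 2 :, nx // 2]
        myo = np.flatnonzero(np.abs(col - 0.6) < 0.1)
        measured = (myo[-1] - myo[0] + 1) * ps
        expect = mouse_spec.wall_thickness_mm("mid") * (1 + mouse_spec.radial_thickening_frac)
        assert abs(measured - expect) <= ps

    def test_long_axis_extent_shortens(self):
        spec = PhantomSpec.mouse(long_shortening_frac=0.15, circ_shortening_frac=0.0,
                                 radial_thickening_frac=0.0)
        ref = render_cine(spec, deform(spec, 0), "long_axis",
                          noise_sd=0.0, texture_amp=0.0, psf_sigma_px=0.0)
        last = render_cine(spec, deform(spec, spec.n_frames - 1), "long_axis",
                           noise_sd=0.0, texture_amp=0.0, psf_sigma_px=0.0)
        ps = spec.pixel_spacing_mm

        def extent(img):
            rows = np.flatnonzero((img > 0.3).any(axis=1))
            return (rows[-1] - rows[0] + 1) * ps

        assert extent(last) / extent(ref) == pytest.approx(0.85, abs=ps / extent(ref) * 2)


class TestContours:
    def test_circular_contour_points_equidistant(self, mouse_spec):
        cs = make_contours(mouse_spec, 0)
        for level in SA_LEVELS:
            c = cs.sa[(level, "lv_endo")]
            r = np.linalg.norm(c.points - c.centroid, axis=1)
            assert np.allclose(r, mouse_spec.endo_radius_mm[level], atol=1e-9)

    def test_septal_segment_shared_point_for_point(self, mouse_spec):
        cs = make_contours(mouse_spec, 7)
        i0, i1 = cs.rv_insertion_indices
        lv_epi = cs.sa[("mid", "lv_epi")].points
        rv_endo = cs.sa[("mid", "rv_endo")].points
        n_sept = len(rv_endo) - cs.rv_freewall_points
        # the septal block of rv_endo is drawn from lv_epi points
        sept = rv_endo[:n_sept]
        d = np.min(np.linalg.norm(sept[:, None, :] - lv_epi[None, :, :], axis=-1), axis=1)
        assert d.max() < 1e-12

    def test_contour_perimeter_matches_analytic_circumference(self, mouse_spec):
        cs = make_contours(mouse_spec, 0, n_points=256)
        c = cs.sa[("mid", "lv_endo")]
        analytic = 2 * np.pi * mouse_spec.endo_radius_mm["mid"]
        assert abs(c.perimeter() - analytic) / analytic < 1e-3


class TestPressure:
    def test_recorded_max_strictly_below_pmax(self):
        w = simulate_pressure(PressureParams())
        assert w.pressure.max() < w.truth["pmax"]

    def test_ground_truth_ees_self_consistent(self):
        params = PressureParams(pmax_true=75, pes_true=30, stroke_volume_true_ml=30)
        w = simulate_pressure(params)
        assert w.truth["ees"] == pytest.approx(1.5)
        assert (w.truth["pmax"] - w.truth["pes"]) / w.truth["sv"] == w.truth["ees"]

    def test_ees_truth_is_heart_rate_free(self):
        e = []
        for hr in (100.0, 400.0):
            p = PressureParams(heart_rate_bpm=hr, sampling_hz=2000.0)
            e.append(simulate_pressure(p).truth["ees"])
        assert e[0] == e[1]

    def test_landmarks_match_detection_within_two_samples(self):
        w = simulate_pressure(PressureParams())
        lm = detect_landmarks(w)
        assert abs(lm.end_diastole - w.landmarks.end_diastole) <= 2
        assert abs(lm.ejection_onset - w.landmarks.ejection_onset) <= 2
        assert abs(lm.end_systole - w.landmarks.end_systole) <= 2

    def test_undersampled_cycle_rejected(self):
        with pytest.raises(ConfigurationError):
            PressureParams(sampling_hz=25.0, heart_rate_bpm=100.0)

    def test_invalid_pressure_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            PressureParams(pmax_true=30.0, pes_true=40.0)


class TestCohortSampling:
    def test_large_sample_mean_converges(self):
        cfg = CohortConfig(
            groups=(GroupBlock("pab", "mouse", 100000,
                               {"peak_torsion_rate_deg_per_tau": (0.84, 0.6)}),),
            seed=7,
        )
        table = sample_cohort(cfg)
        m = table["peak_torsion_rate_deg_per_tau"].mean()
        # CLT: SE = 0.6/sqrt(1e5) ~ 0.0019; 3 SE bound
        assert abs(m - 0.84) < 0.01

    def test_zero_sd_gives_identical_subjects(self):
        cfg = CohortConfig(groups=(GroupBlock("g", "mouse", 5, {"m": (3.0, 0.0)}),), seed=0)
        table = sample_cohort(cfg)
        assert (table["m"] == 3.0).all()

    def test_requested_correlation_is_realized(self):
        cfg = CohortConfig(
            groups=(GroupBlock("g", "human", 10000,
                               {"a": (0.0, 1.0), "b": (0.0, 1.0)},
                               correlations=(("a", "b", 0.9),)),),
            seed=3,
        )
        table = sample_cohort(cfg)
        r = np.corrcoef(table["a"], table["b"])[0, 1]
        assert abs(r - 0.9) < 0.02

    def test_deterministic_under_seed(self):
        from cardiotwist.phantom import reference_cohort_config

        t1 = sample_cohort(reference_cohort_config(5))
        t2 = sample_cohort(reference_cohort_config(5))
        assert t1.equals(t2)

    def test_singular_correlation_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(
                groups=(GroupBlock("g", "human", 5, {"a": (0, 1), "b": (0, 1)},
                                   correlations=(("a", "b", 1.5),)),),
            ).validate()
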