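"""Cortex straightening, FWHM, peak-to-peak and overhang statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexpen import cortex_profile, synthgen
from cortexpen.cortex_profile import (
    FWHMResult,
    ProfileRejected,
    StraightenedCortex,
    TransverseProfileBin,
    aggregate_cell,
    bin_profiles,
    curvature_broadening_bound,
    detect_cortex,
    measure_fwhm,
    overhang,
    overhang_symmetric,
    peak_to_peak,
    straighten,
)
from cortexpen.smlm_core import RenderedImage

FWHM_SIGMA = 2 * np.sqrt(2 * np.log(2))


def gaussian_profile(axis, center=0.0, sigma=50.0, amplitude=1.0, background=0.0):
    return background + amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2)


class TestMeasureFWHM:
    axis = np.arange(-600.0, 601.0, 5.0)

    def test_gaussian_fwhm_closed_form(self):
        res = measure_fwhm(self.axis, gaussian_profile(self.axis, sigma=50.0))
        assert res.fwhm == pytest.approx(FWHM_SIGMA * 50.0, abs=0.5)
        assert res.peak_position == pytest.approx(0.0, abs=0.5)

    def test_triangle_fwhm_equals_half_width(self):
        prof = np.clip(1 - np.abs(self.axis) / 100.0, 0, None)
        res = measure_fwhm(self.axis, prof)
        assert res.fwhm == pytest.approx(100.0, abs=1.0)

    def test_monotone_ramp_rejected(self):
        with pytest.raises(ProfileRejected, match="interior"):
            measure_fwhm(self.axis, np.linspace(0, 1, len(self.axis)))

    def test_truncated_profile_rejected(self):
        prof = gaussian_profile(self.axis, center=580.0, sigma=60.0)
        with pytest.raises(ProfileRejected, match="crossing|interior"):
            measure_fwhm(self.axis, prof)

    def test_background_subtracted_before_halfmax(self):
        res0 = measure_fwhm(self.axis, gaussian_profile(self.axis, sigma=50.0))
        res1 = measure_fwhm(
            self.axis, gaussian_profile(self.axis, sigma=50.0, background=3.0)
        )
        assert res1.fwhm == pytest.approx(res0.fwhm, abs=1.0)
        assert res1.background == pytest.approx(3.0, abs=0.01)


class TestOverhangAndPeakToPeak:
    axis = np.arange(-600.0, 601.0, 5.0)

    def _fwhm(self, lo, hi):
        return FWHMResult(
            peak_position=(lo + hi) / 2, fwhm_lo=lo, fwhm_hi=hi,
            background=0.0, peak_height=1.0,
        )

    def test_identical_profiles_zero(self):
        res = measure_fwhm(self.axis, gaussian_profile(self.axis))
        assert overhang(res, res) == 0.0
        assert peak_to_peak(res, res) == 0.0

    def test_interval_examples(self):
        a = self._fwhm(-100, 100)
        assert overhang(a, self._fwhm(-40, 180)) == pytest.approx(36.36, abs=0.01)
        assert overhang(a, self._fwhm(-120, 60)) == pytest.approx(-22.22, abs=0.01)

    def test_interval_examples_match_rasterized_oracle(self):
        # 1-nm rasterization of the signed non-overlap beyond the actin edge
        def raster(a_lo, a_hi, t_lo, t_hi):
            x = np.arange(-300.0, 300.0, 1.0)
            if t_hi >= a_hi:
                n = ((x > a_hi) & (x >= t_lo) & (x <= t_hi)).sum()
            else:
                n = -((x > t_hi) & (x <= a_hi)).sum()
            return 100.0 * n / (t_hi - t_lo)

        a = self._fwhm(-100, 100)
        for t_lo, t_hi in [(-40, 180), (-120, 60)]:
            assert overhang(a, self._fwhm(t_lo, t_hi)) == pytest.approx(
                raster(-100, 100, t_lo, t_hi), abs=0.6
            )

    def test_shifted_gaussian_peak_to_peak(self):
        a = measure_fwhm(self.axis, gaussian_profile(self.axis))
        t_deep = measure_fwhm(self.axis, gaussian_profile(self.axis, center=30.0))
        t_memb = measure_fwhm(self.axis, gaussian_profile(self.axis, center=-30.0))
        assert peak_to_peak(a, t_deep) == pytest.approx(30.0, abs=1.0)
        assert peak_to_peak(a, t_memb) == pytest.approx(-30.0, abs=1.0)
        assert overhang(a, t_memb) < 0

    def test_degenerate_target_rejected(self):
        a = self._fwhm(-100, 100)
        bad = FWHMResult(0.0, 50.0, 50.0, 0.0, 1.0)
        with pytest.raises(ProfileRejected):
            overhang(a, bad)

    def test_symmetric_variant_counts_both_sides(self):
        a = self._fwhm(-100, 100)
        t = self._fwhm(-120, 180)  # 20 beyond membrane side, 80 beyond cytoplasm
        assert overhang_symmetric(a, t) == pytest.approx(100 * 100 / 300, abs=1e-9)
        assert overhang(a, t) == pytest.approx(100 * 80 / 300, abs=1e-9)

    @given(
        shift=st.floats(-100, 100),
        scale_a=st.floats(0.1, 10),
        scale_t=st.floats(0.1, 10),
        center_t=st.floats(-50, 50),
        sigma_t=st.floats(30, 90),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariance_under_shift_and_rescale(
        self, shift, scale_a, scale_t, center_t, sigma_t
    ):
        """Overhang is invariant to a common rigid shift and per-channel scaling."""
        axis = np.arange(-600.0, 601.0, 5.0)
        a0 = measure_fwhm(axis, gaussian_profile(axis))
        t0 = measure_fwhm(axis, gaussian_profile(axis, center_t, sigma_t))
        a1 = measure_fwhm(
            axis, scale_a * gaussian_profile(axis, 0.0 + shift)
        )
        t1 = measure_fwhm(
            axis, scale_t * gaussian_profile(axis, center_t + shift, sigma_t)
        )
        assert overhang(a1, t1) == pytest.approx(overhang(a0, t0), abs=0.5)
        assert peak_to_peak(a1, t1) == pytest.approx(peak_to_peak(a0, t0), abs=1.0)


def horizontal_band_image(ny=120, nx=200, px=10.0, center_row=60, sigma_px=8.0):
    rows = np.arange(ny)
    prof = np.exp(-0.5 * ((rows - center_row) / sigma_px) ** 2)
    return RenderedImage(np.tile(prof[:, None], (1, nx)), px)


class TestStraighten:
    def test_straight_band_is_identity_crop(self):
        img = horizontal_band_image()
        seeds = np.column_stack(
            [np.linspace(200, 1800, 12), np.full(12, 605.0)]
        )
        contour = detect_cortex(img, seeds, closed=False, cytoplasm_side="positive")
        st_ = straighten({"actin": img}, contour, half_width_nm=400.0)
        # every interior row reproduces the transverse Gaussian profile
        mid = st_.channels["actin"][st_.valid_rows]
        expected = np.exp(-0.5 * (st_.axis / 80.0) ** 2)
        err = np.abs(mid - expected[None, :]).max()
        assert err < 0.02

    def test_rotation_invariance(self):
        # band through the image centre so the rotated ridge stays centred
        img = horizontal_band_image(ny=300, nx=300, center_row=150)
        seeds_h = np.column_stack([np.linspace(500, 2500, 10), np.full(10, 1505.0)])
        c_h = detect_cortex(img, seeds_h, closed=False, cytoplasm_side="positive")
        p_h = bin_profiles(straighten({"a": img}, c_h, 400.0), 200.0)

        # rotate the band by 30 degrees via a rotated image grid
        from scipy.ndimage import rotate

        rot = RenderedImage(rotate(img.data, 30.0, reshape=True, order=1), 10.0)
        ang = np.radians(30.0)
        # seed along the rotated ridge through the image centre
        c0 = np.array(rot.data.shape[::-1]) * 10.0 / 2
        tvals = np.linspace(-800, 800, 10)
        direction = np.array([np.cos(ang), -np.sin(ang)])
        seeds_r = c0 + tvals[:, None] * direction
        c_r = detect_cortex(rot, seeds_r, closed=False, cytoplasm_side="positive")
        p_r = bin_profiles(straighten({"a": rot}, c_r, 400.0), 200.0)

        f_h = measure_fwhm(p_h[0].axis, p_h[0].profiles["a"]).fwhm
        f_r = measure_fwhm(p_r[1].axis, p_r[1].profiles["a"]).fwhm
        assert f_r == pytest.approx(f_h, rel=0.03)

    def test_circular_contour_recovered_within_pixel(self, rendered_cortex):
        images, truth = rendered_cortex
        contour = detect_cortex(images["actin"])
        c = contour.points.mean(axis=0)
        r = np.hypot(*(contour.points - c).T)
        expected = truth.cell_radius - truth.actin_band.depth_nm
        assert abs(r.mean() - expected) < images["actin"].pixel_size


class TestBinning:
    def _straightened(self, n_rows, valid=None):
        axis = np.arange(-300.0, 301.0, 10.0)
        arcs = np.arange(n_rows) * 10.0
        data = np.tile(gaussian_profile(axis), (n_rows, 1))
        return StraightenedCortex(
            arcs, axis, {"a": data},
            np.ones(n_rows, bool) if valid is None else valid,
        )

    def test_uniform_band_gives_identical_bins(self):
        bins = bin_profiles(self._straightened(60), 200.0)
        assert len(bins) == 3
        np.testing.assert_allclose(bins[0].profiles["a"], bins[2].profiles["a"])

    def test_incomplete_trailing_bin_dropped(self):
        bins = bin_profiles(self._straightened(50), 200.0)  # 2.5 bins
        assert len(bins) == 2

    def test_bin_with_flagged_rows_excluded(self):
        valid = np.ones(60, bool)
        valid[25] = False
        bins = bin_profiles(self._straightened(60, valid), 200.0)
        assert len(bins) == 2


class TestAggregate:
    def _bin(self, center_t=0.0):
        axis = np.arange(-600.0, 601.0, 10.0)
        return TransverseProfileBin(
            0.0, axis,
            {
                "actin": gaussian_profile(axis),
                "target": gaussian_profile(axis, center=center_t),
            },
        )

    def test_equal_bins_give_their_value(self):
        res = aggregate_cell([self._bin(20.0)] * 5)
        assert res.n_bins_accepted == 5
        assert res.mean_peak_to_peak == pytest.approx(20.0, abs=1.0)

    def test_fewer_than_three_bins_excludes_cell(self):
        with pytest.raises(ValueError, match="excluded"):
            aggregate_cell([self._bin()] * 2)

    def test_rejected_bins_counted_by_reason(self):
        axis = np.arange(-600.0, 601.0, 10.0)
        bad = TransverseProfileBin(
            0.0, axis,
            {"actin": np.linspace(0, 1, len(axis)),
             "target": gaussian_profile(axis)},
        )
        res = aggregate_cell([self._bin()] * 3 + [bad])
        assert res.n_bins_total == 4
        assert res.n_bins_accepted == 3
        assert sum(res.rejections.values()) == 1


class TestSceneRecovery:
    def test_same_band_control_near_zero(self):
        """Actin/actin-style control: identical bands give ~0% overhang."""
        from conftest import measure_scene_overhang

        vals = [measure_scene_overhang(100.0, 200.0, s)[1].mean_overhang
                for s in range(3)]
        assert abs(np.mean(vals)) < 3.0

    def test_rendered_fwhm_at_least_true_fwhm(self, rendered_cortex):
        images, truth = rendered_cortex
        res = cortex_profile.analyze_cortex(images)
        assert res.mean_actin_fwhm >= truth.actin_band.fwhm_nm - 15.0
        # and the excess shrinks when localization uncertainty shrinks
        spec = synthgen.CortexSceneSpec(
            uncertainty_mean=5.0, uncertainty_sd=2.0,
            target_band=synthgen.BandSpec(140.0, 220.0, 15000),
        )
        a, t, _ = synthgen.gen_smlm_cortex(spec, 11)
        from conftest import render_two_channel

        res_sharp = cortex_profile.analyze_cortex(render_two_channel(a, t))
        assert res_sharp.mean_actin_fwhm <= res.mean_actin_fwhm + 3.0


class TestCurvatureBound:
    def test_printed_bound_for_small_cell(self):
        # R = 5 um, 200 nm focal slab: per-edge shift 1 nm, bound 2 nm
        bound = curvature_broadening_bound(5000.0, 200.0)
        assert bound == pytest.approx(2.0, abs=0.01)
        per_edge = bound / 2
        assert per_edge == pytest.approx(5000 - np.sqrt(5000**2 - 100**2), abs=1e-9)

    def test_zero_slab_zero_bound(self):
        assert curvature_broadening_bound(5000.0, 0.0) == 0.0

    def test_monotonically_decreasing_in_radius(self):
        radii = np.linspace(1000.0, 20000.0, 40)
        bounds = [curvature_broadening_bound(r, 200.0) for r in radii]
        assert np.all(np.diff(bounds) < 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            curvature_broadening_bound(90.0, 200.0)
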