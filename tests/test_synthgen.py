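"""Generator correctness: ground truth, determinism, forward-model contracts."""

import numpy as np
import pandas as pd
import pytest

from cortexpen import synthgen
from cortexpen.confocal_quant import myosin_step_model, step_convolution_model
from cortexpen.synthgen import (
    BandSpec,
    ConfocalCellSpec,
    CortexSceneSpec,
    ForceCurveSpec,
    LinescanSpec,
    MinifilSceneSpec,
    true_overhang,
)


def rasterized_overhang(actin: BandSpec, target: BandSpec, step=1.0):
    """Independent 1-nm rasterized computation of the signed cytoplasmic overhang."""
    a_lo, a_hi = actin.interval
    t_lo, t_hi = target.interval
    x = np.arange(min(a_lo, t_lo) - 5, max(a_hi, t_hi) + 5, step)
    in_target = (x >= t_lo) & (x <= t_hi)
    beyond = in_target & (x > a_hi)
    n_beyond = beyond.sum()
    if t_hi < a_hi:  # retracted edge: count the signed gap instead
        gap = (x > t_hi) & (x <= a_hi)
        n_beyond = -gap.sum()
    return 100.0 * n_beyond * step / (t_hi - t_lo)


class TestTrueOverhang:
    def test_identical_bands_have_zero_overhang(self):
        band = BandSpec(100.0, 200.0, 10)
        assert true_overhang(band, band) == 0.0

    @pytest.mark.parametrize(
        "actin,target",
        [
            ((100.0, 200.0), (140.0, 220.0)),
            ((100.0, 200.0), (60.0, 180.0)),
            ((100.0, 200.0), (170.0, 260.0)),
            ((150.0, 250.0), (150.0, 200.0)),
        ],
    )
    def test_interval_arithmetic_matches_rasterized_oracle(self, actin, target):
        a = BandSpec(actin[0], actin[1], 10)
        t = BandSpec(target[0], target[1], 10)
        assert true_overhang(a, t) == pytest.approx(rasterized_overhang(a, t), abs=0.5)

    def test_documented_example_value(self):
        # actin FWHM 200 at depth 100, target FWHM 220 centred 40 nm deeper:
        # target interval [30, 250], actin [0, 200] -> 50/220
        a = BandSpec(100.0, 200.0, 10)
        t = BandSpec(140.0, 220.0, 10)
        assert true_overhang(a, t) == pytest.approx(100 * 50 / 220, abs=1e-9)


class TestSmlmCortex:
    def test_seed_determinism(self):
        spec = CortexSceneSpec(actin_band=BandSpec(100, 200, 500), n_frames=100)
        a1, t1, _ = synthgen.gen_smlm_cortex(spec, 7)
        a2, t2, _ = synthgen.gen_smlm_cortex(spec, 7)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)
        a3, _, _ = synthgen.gen_smlm_cortex(spec, 8)
        assert not a1["x"].equals(a3["x"])

    def test_band_radius_statistics(self):
        spec = CortexSceneSpec(actin_band=BandSpec(100, 200, 20000))
        a, _, gt = synthgen.gen_smlm_cortex(spec, 1)
        r = np.hypot(a["x"] - 3000, a["y"] - 3000)
        assert r.mean() == pytest.approx(2400, abs=3 * 2.0)
        # radial SD: band sigma + localization noise in quadrature
        expected_sd = np.sqrt((200 / 2.3548) ** 2 + 20**2 + 10**2)
        assert r.std() == pytest.approx(expected_sd, rel=0.05)

    def test_zero_drift_identity_affine_is_undistorted(self):
        spec = CortexSceneSpec(actin_band=BandSpec(100, 200, 2000), n_frames=100)
        a_plain, _, _ = synthgen.gen_smlm_cortex(spec, 5)
        spec2 = CortexSceneSpec(
            actin_band=BandSpec(100, 200, 2000),
            n_frames=100,
            drift=np.zeros((100, 2)),
        )
        a_zero, _, _ = synthgen.gen_smlm_cortex(spec2, 5)
        np.testing.assert_allclose(a_plain["x"], a_zero["x"])

    def test_drift_applied_cumulatively(self):
        drift = synthgen.linear_drift(100, (100.0, 0.0))
        spec = CortexSceneSpec(
            actin_band=BandSpec(100, 200, 5000), n_frames=100, drift=drift
        )
        a, _, _ = synthgen.gen_smlm_cortex(spec, 5)
        spec0 = CortexSceneSpec(actin_band=BandSpec(100, 200, 5000), n_frames=100)
        a0, _, _ = synthgen.gen_smlm_cortex(spec0, 5)
        shift = a["x"].to_numpy() - a0["x"].to_numpy()
        np.testing.assert_allclose(shift, drift[a["frame"].to_numpy(int), 0])

    def test_beads_in_every_frame_both_channels(self):
        spec = CortexSceneSpec(
            actin_band=BandSpec(100, 200, 500),
            n_frames=50,
            beads=np.array([[500.0, 500.0], [5000.0, 900.0]]),
        )
        a, t, gt = synthgen.gen_smlm_cortex(spec, 2)
        for tab in (a, t):
            bead_rows = tab[tab["intensity"] > 10000]
            assert set(bead_rows["frame"]) == set(range(50))
            assert len(bead_rows) == 100
        assert gt.beads.shape == (2, 2)

    def test_chromatic_affine_applied_to_target_only(self):
        from cortexpen.smlm_core import AffineTransform2D

        tf = AffineTransform2D.from_params(shift=(50.0, -20.0))
        kw = dict(actin_band=BandSpec(100, 200, 2000), n_frames=50)
        a1, t1, _ = synthgen.gen_smlm_cortex(CortexSceneSpec(**kw), 3)
        a2, t2, _ = synthgen.gen_smlm_cortex(
            CortexSceneSpec(**kw, chromatic_affine=tf), 3
        )
        np.testing.assert_allclose(a1["x"], a2["x"])
        np.testing.assert_allclose(t2["x"], t1["x"] + 50.0)
        np.testing.assert_allclose(t2["y"], t1["y"] - 20.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="FWHM"):
            BandSpec(100, -1, 10)
        with pytest.raises(ValueError, match="count"):
            BandSpec(100, 200, 0)
        with pytest.raises(ValueError, match="radius"):
            CortexSceneSpec(cell_radius=-5)


class TestSimMinifilaments:
    def test_projected_length_ground_truth(self):
        spec = MinifilSceneSpec(
            n_filaments=3, theta_values_deg=np.array([0.0, 20.0, 90.0]),
            poisson_noise=False, read_noise_sd=0.0,
        )
        _, truths = synthgen.gen_sim_minifilaments(spec, 0)
        lengths = {round(t.theta_deg): t for t in truths}
        assert lengths[0].projected_length_nm == pytest.approx(317.0)
        assert lengths[20].projected_length_nm == pytest.approx(297.9, abs=0.05)
        assert lengths[90].projected_length_nm == pytest.approx(0.0, abs=1e-9)
        assert not lengths[90].detectable
        # emitted head coordinates agree with the recorded projection
        t20 = lengths[20]
        assert np.linalg.norm(t20.head1_nm - t20.head2_nm) == pytest.approx(
            t20.projected_length_nm, abs=1e-9
        )

    def test_mean_projected_length_matches_expectation(self):
        # E[cos theta] for theta ~ U[0, 30 deg] = sin(30deg)/(pi/6)
        theta_max = np.radians(30.0)
        expected = 317.0 * np.sin(theta_max) / theta_max
        spec = MinifilSceneSpec(
            n_filaments=200, image_size_px=2048, poisson_noise=False
        )
        lengths = []
        for seed in range(50):
            _, truths = synthgen.gen_sim_minifilaments(spec, seed)
            lengths.extend(t.projected_length_nm for t in truths)
        lengths = np.asarray(lengths)  # 10^4 filaments
        sem = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert lengths.mean() == pytest.approx(expected, abs=3 * sem)

    def test_density_warning(self):
        with pytest.warns(UserWarning, match="density"):
            MinifilSceneSpec(n_filaments=500, image_size_px=64, pixel_size_nm=40.0)

    def test_determinism(self):
        spec = MinifilSceneSpec(n_filaments=5)
        img1, _ = synthgen.gen_sim_minifilaments(spec, 9)
        img2, _ = synthgen.gen_sim_minifilaments(spec, 9)
        np.testing.assert_array_equal(img1, img2)


class TestLinescan:
    def test_zero_noise_matches_fitter_forward_model(self):
        spec = LinescanSpec(noise_sd=0.0)
        x, actin, myo, gt = synthgen.gen_linescan(spec, 0)
        model_a = step_convolution_model(
            x, spec.x_m_nm, spec.h_actin_nm, spec.i_out, spec.i_cort, spec.i_in,
            spec.psf_sigma_nm,
        )
        model_m = myosin_step_model(
            x, spec.x_m_nm + spec.h_actin_nm, spec.h_myo_nm,
            spec.myo_out, spec.myo_peak, spec.myo_in, spec.psf_sigma_nm,
        )
        assert np.max(np.abs(actin - model_a)) < 1e-9 * actin.max()
        assert np.max(np.abs(myo - model_m)) < 1e-9 * myo.max()

    def test_delta_psf_gives_exact_steps(self):
        spec = LinescanSpec(psf_sigma_nm=0.0, noise_sd=0.0)
        x, actin, _, _ = synthgen.gen_linescan(spec, 0)
        plateau = x[(actin == spec.i_cort)]
        assert plateau.max() - plateau.min() == pytest.approx(
            spec.h_actin_nm, abs=spec.pitch_nm
        )

    def test_myosin_free_length_ground_truth(self):
        spec = LinescanSpec(h_actin_nm=230.0, h_myo_nm=150.0)
        *_, gt = synthgen.gen_linescan(spec, 0)
        assert gt.myosin_free_length_nm == pytest.approx(80.0)
        spec_full = LinescanSpec(h_actin_nm=230.0, h_myo_nm=230.0)
        *_, gt_full = synthgen.gen_linescan(spec_full, 0)
        assert gt_full.myosin_free_length_nm == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            LinescanSpec(h_actin_nm=-1)
        with pytest.raises(ValueError):
            LinescanSpec(h_actin_nm=200, h_myo_nm=250)
        with pytest.raises(ValueError):
            LinescanSpec(psf_sigma_nm=-5)


class TestForceCurve:
    def test_plateau_and_peak_shape(self):
        spec = ForceCurveSpec(noise_sd_nN=0.0)
        curve = synthgen.gen_force_curve(spec, 0)
        t = curve["time"].to_numpy()
        f = curve["force"].to_numpy()
        assert f[t < spec.compression_time_s].max() == pytest.approx(spec.baseline_nN)
        assert f.max() == pytest.approx(spec.peak_nN, rel=0.01)
        late = f[t > spec.compression_time_s + 8 * spec.relax_tau_s]
        assert late == pytest.approx(spec.plateau_nN, rel=1e-3)

    def test_drug_transient_scales_force(self):
        spec = ForceCurveSpec(
            duration_s=200.0, drug_time_s=60.0,
            drug_response=synthgen.drug_transient(0.3, -0.5, tau_s=20.0),
            relax_tau_s=2.0, noise_sd_nN=0.0,
        )
        curve = synthgen.gen_force_curve(spec, 0)
        t = curve["time"].to_numpy()
        f = curve["force"].to_numpy()
        just_after = f[np.searchsorted(t, 60.0) + 1]
        assert just_after == pytest.approx(1.3 * spec.plateau_nN, rel=0.02)
        assert f[-1] == pytest.approx(0.5 * spec.plateau_nN, rel=0.05)

    def test_drug_before_relaxation_rejected(self):
        with pytest.raises(ValueError, match="relaxation"):
            ForceCurveSpec(drug_time_s=15.0)


class TestConfocalCells:
    def test_overlapping_cells_rejected(self):
        cells = [
            ConfocalCellSpec((50.0, 50.0), 30.0, 10.0),
            ConfocalCellSpec((80.0, 80.0), 30.0, 10.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            synthgen.gen_confocal_cell_image(cells)

    def test_masks_and_intensities_recorded(self):
        cells = [ConfocalCellSpec((60.0, 60.0), 25.0, 10.0),
                 ConfocalCellSpec((180.0, 180.0), 30.0, 20.0)]
        img, gt = synthgen.gen_confocal_cell_image(cells, noise_sd=0.0, seed=0)
        assert len(gt.masks) == 2
        assert gt.cortex_intensities == [10.0, 20.0]
        # mask area matches the membrane disk
        assert gt.masks[0].sum() == pytest.approx(np.pi * 25**2, rel=0.02)
        # peak intensity at the membrane
        assert img.max() == pytest.approx(20.0 + img[gt.masks[1]].min(), rel=0.3)

    def test_zero_cells_gives_background_only(self):
        img, gt = synthgen.gen_confocal_cell_image(
            [], background_offset=1.0, noise_sd=0.0, seed=0
        )
        assert gt.masks == []
        assert img.max() <= 1.5 + 1e-9
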