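"""Correction chain round trips against rendered ground truth."""

import numpy as np
import pytest

from nightshift.calibration import (
    CalibrationError,
    CalibrationModel,
    atmospheric_correct,
    calibrate_frame,
    correct_flatfield,
    correct_linearity,
    decode,
    estimate_constants,
    mask_clouds,
    photometric_calibrate,
    radiometric_correct,
    spectral_characterize,
)
from nightshift.scene import (
    DistortionConfig,
    render_calibration_field,
    render_frame,
    render_viirs,
)

from _helpers import geom


@pytest.fixture(scope="module")
def distorted_raw(small_maps, camera):
    m1, _ = small_maps
    return render_frame(m1, camera, geom(), DistortionConfig(), seed=21)


@pytest.fixture(scope="module")
def truth_model():
    return CalibrationModel.from_distortions(DistortionConfig())


def _clean_frame(small_maps, camera, **geom_kw):
    m1, _ = small_maps
    d = DistortionConfig.none()
    d.n_sources = 0
    raw = render_frame(m1, camera, geom(**geom_kw), d, seed=0)
    return raw, decode(raw)


class TestLinearity:
    def test_identity_below_knee(self, small_maps, camera, truth_model):
        _, frame = _clean_frame(small_maps, camera)
        frame.values[:] = np.minimum(frame.values, truth_model.knee)
        out = correct_linearity(frame, truth_model)
        np.testing.assert_allclose(out.values, frame.values, atol=1e-9)

    def test_count_exactly_at_knee_is_unchanged(self, truth_model):
        from nightshift.calibration import Frame

        v = np.full((3, 4, 4), truth_model.knee)
        frame = Frame(
            values=v.copy(),
            valid=np.ones((4, 4), bool),
            reasons=np.zeros((4, 4), np.uint8),
            geometry=geom(frame=(4, 4)),
            window=(0, 0),
            grid=None,
            control_points=np.zeros((4, 4)),
        )
        out = correct_linearity(frame, truth_model)
        np.testing.assert_allclose(out.values, v, atol=1e-9)

    def test_rolloff_round_trip_below_saturation(self, truth_model):
        from nightshift.calibration import Frame

        d = DistortionConfig()
        true_counts = np.linspace(100, d.full_well * 0.99, 48).reshape(3, 4, 4)
        distorted = d.apply_nonlinearity(true_counts)
        frame = Frame(
            values=distorted.copy(),
            valid=np.ones((4, 4), bool),
            reasons=np.zeros((4, 4), np.uint8),
            geometry=geom(frame=(4, 4)),
            window=(0, 0),
            grid=None,
            control_points=np.zeros((4, 4)),
        )
        out = correct_linearity(frame, truth_model)
        ok = out.valid  # pixels not flagged saturated
        rel = np.abs(out.values[:, ok] - true_counts[:, ok]) / true_counts[:, ok]
        assert rel.max() < 0.01

    def test_saturated_pixels_are_flagged(self, truth_model):
        from nightshift.calibration import Frame

        d = DistortionConfig()
        hot = d.apply_nonlinearity(np.full((3, 2, 2), d.full_well * 3.0))
        frame = Frame(
            values=hot,
            valid=np.ones((2, 2), bool),
            reasons=np.zeros((2, 2), np.uint8),
            geometry=geom(frame=(2, 2)),
            window=(0, 0),
            grid=None,
            control_points=np.zeros((4, 4)),
        )
        out = correct_linearity(frame, truth_model)
        assert not out.valid.any()


class TestFlatField:
    def test_unit_flatfield_is_identity(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        model = CalibrationModel(vignette_a2=0.0, vignette_a4=0.0)
        out = correct_flatfield(frame, model)
        np.testing.assert_array_equal(out.values, frame.values)

    def test_corner_with_half_vignette_doubles(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        ff = np.ones(frame.shape)
        ff[0, 0] = 0.5
        model = CalibrationModel(flatfield=ff)
        out = correct_flatfield(frame, model)
        np.testing.assert_allclose(out.values[:, 0, 0], frame.values[:, 0, 0] * 2)

    def test_uniform_scene_recovered_from_vignetted_render(self):
        # a uniform radiance field through the vignette, then corrected,
        # should be uniform again (CV < 2%)
        d = DistortionConfig()
        vign = d.vignette((64, 64))
        counts = 1000.0 * vign[None] * np.ones((3, 64, 64))
        from nightshift.calibration import Frame

        frame = Frame(
            values=counts,
            valid=np.ones((64, 64), bool),
            reasons=np.zeros((64, 64), np.uint8),
            geometry=geom(),
            window=(0, 0),
            grid=None,
            control_points=np.zeros((4, 4)),
        )
        out = correct_flatfield(frame, CalibrationModel.from_distortions(d))
        cv = out.values[1].std() / out.values[1].mean()
        assert cv < 0.02

    def test_nonpositive_flatfield_rejected(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        model = CalibrationModel(flatfield=np.zeros(frame.shape))
        with pytest.raises(ValueError, match="positive"):
            correct_flatfield(frame, model)


class TestSpectralCharacterization:
    def test_identity_matrix_is_identity(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        out = spectral_characterize(frame, CalibrationModel(crosstalk=np.eye(3)))
        np.testing.assert_allclose(out.values, frame.values, atol=1e-12)

    def test_known_leak_round_trip(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        leak = np.array([[1.0, 0.0, 0.0], [0.0, 0.9, 0.0], [0.0, 0.1, 1.0]])
        mixed = frame.copy()
        mixed.values = np.einsum("ij,jhw->ihw", leak, frame.values)
        out = spectral_characterize(mixed, CalibrationModel(crosstalk=leak))
        np.testing.assert_allclose(out.values, frame.values, atol=1e-6)

    def test_zero_frame_stays_zero(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        frame.values[:] = 0
        out = spectral_characterize(frame, CalibrationModel(crosstalk=np.eye(3) * 0.9))
        assert out.values.max() == 0.0

    def test_singular_matrix_rejected(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        singular = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            spectral_characterize(frame, CalibrationModel(crosstalk=singular))


class TestPhotometricCalibration:
    def test_constants_recovered_within_two_percent(self, camera, truth_model):
        star_field = render_calibration_field(camera, geom(), DistortionConfig(), seed=21)
        constants = estimate_constants(star_field, truth_model)
        true_k = np.asarray(DistortionConfig().instrumental_constants)
        assert np.abs(constants / true_k - 1).max() < 0.02

    def test_exposure_change_leaves_constants_invariant(self, camera, truth_model):
        d = DistortionConfig()
        d.read_noise, d.shot_var_per_count = 0.0, 0.0
        ks = []
        for exposure in (0.2, 0.4):
            star_field = render_calibration_field(
                camera, geom(exposure_s=exposure), d, seed=4
            )
            ks.append(estimate_constants(star_field, truth_model))
        assert np.abs(ks[1] / ks[0] - 1).max() < 0.01

    def test_too_few_usable_sources_raise(self, distorted_raw, truth_model):
        frame = decode(distorted_raw)
        with pytest.raises(CalibrationError, match="usable reference sources"):
            photometric_calibrate(frame, distorted_raw.truth["sources"][:2])

    def test_saturated_source_is_excluded(self, small_maps, camera, truth_model):
        m1, _ = small_maps
        raw = render_frame(m1, camera, geom(), DistortionConfig(), seed=21)
        frame = decode(raw)
        frame = correct_linearity(frame, truth_model)
        # saturate the aperture of the first three sources
        for sr, sc, _ in raw.truth["sources"][:3]:
            frame.invalidate(
                np.fromfunction(
                    lambda r, c: np.hypot(r - sr, c - sc) <= 3, frame.shape
                ),
                1,
            )
        frame = correct_flatfield(frame, truth_model)
        frame = spectral_characterize(frame, truth_model)
        frame.log["iso_ref"] = truth_model.iso_ref
        frame.log["lens_transmittance"] = truth_model.lens_transmittance
        constants = photometric_calibrate(frame, raw.truth["sources"])
        assert frame.log["n_sources_excluded"] >= 3
        assert constants.shape == (3,)


class TestRadiometricAndAtmospheric:
    def test_zero_counts_give_zero_radiance(self, small_maps, camera, truth_model):
        _, frame = _clean_frame(small_maps, camera)
        frame.values[:] = 0
        out = radiometric_correct(frame, np.array([1e-4, 1e-4, 1e-4]), truth_model)
        assert out.units == "radiance"
        assert np.nanmax(out.values) == 0.0

    def test_invalid_constants_rejected(self, small_maps, camera, truth_model):
        _, frame = _clean_frame(small_maps, camera)
        with pytest.raises(ValueError, match="positive"):
            radiometric_correct(frame, np.array([1e-4, -1.0, 1e-4]), truth_model)

    def test_iso_change_cancels_in_radiance(self, small_maps, camera):
        m1, _ = small_maps
        d = DistortionConfig.none()
        d.n_sources = 0
        model = CalibrationModel.from_distortions(d, known_constants=True)
        frames = []
        for iso in (800.0, 1600.0):
            raw = render_frame(m1, camera, geom(iso=iso), d, seed=0)
            frames.append(calibrate_frame(raw, model))
        np.testing.assert_allclose(frames[0].values, frames[1].values, rtol=1e-9)

    def test_unit_transmittance_at_nadir_is_identity(self, small_maps, camera, truth_model):
        _, frame = _clean_frame(small_maps, camera, angle_deg=0.0)
        frame.units = "radiance"
        model = CalibrationModel(t_atm=(1.0, 1.0, 1.0))
        out = atmospheric_correct(frame, model)
        np.testing.assert_array_equal(out.values, frame.values)

    def test_blue_transmittance_scales_inverse(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera, angle_deg=0.0)
        frame.units = "radiance"
        model = CalibrationModel(t_atm=(1.0, 1.0, 0.8))
        out = atmospheric_correct(frame, model)
        np.testing.assert_allclose(out.values[2], frame.values[2] * 1.25, rtol=1e-12)


class TestCloudMasking:
    def test_empty_mask_changes_nothing(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        out = mask_clouds(frame, mask=np.zeros(frame.shape, bool))
        assert out.valid.all()

    def test_requires_mask_or_viirs(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        with pytest.raises(ValueError, match="mask or a VIIRS"):
            mask_clouds(frame)

    def test_heuristic_catches_ground_truth_clouds(self, small_maps, camera):
        m1, _ = small_maps
        viirs = render_viirs(m1)
        model = CalibrationModel.from_distortions(DistortionConfig())
        raw = render_frame(m1, camera, geom(), DistortionConfig(), seed=21)
        cal = calibrate_frame(raw, model, viirs=viirs)
        r0, c0 = cal.window
        truth_cloud = raw.truth["cloud_mask"]
        vwin = viirs.data[0, r0 : r0 + 64, c0 : c0 + 64]
        detectable = truth_cloud & (vwin >= 0.5)
        flagged = cal.reasons == 2  # REASON_CLOUD
        recall = flagged[detectable].mean()
        assert recall >= 0.95

    def test_fully_clouded_frame_is_dropped(self, small_maps, camera):
        _, frame = _clean_frame(small_maps, camera)
        out = mask_clouds(frame, mask=np.ones(frame.shape, bool))
        assert not out.valid.any()


class TestFullChain:
    def test_distortion_free_recovery_is_exact(self, small_maps, camera):
        m1, _ = small_maps
        d = DistortionConfig.none()
        d.n_sources = 0
        model = CalibrationModel.from_distortions(d, known_constants=True)
        raw = render_frame(m1, camera, geom(), d, seed=0)
        cal = calibrate_frame(raw, model)
        truth = raw.truth["radiance"]
        lit = truth[1] > 0
        rel = np.abs(cal.values[:, lit] - truth[:, lit]) / truth[:, lit]
        assert np.median(rel) < 0.01

    def test_calibration_is_homogeneous_of_degree_one(self, small_maps, camera):
        m1, _ = small_maps
        import dataclasses

        scaled = dataclasses.replace(m1, scale=m1.scale * 2.0, weights=m1.weights.copy())
        d = DistortionConfig()
        d.read_noise, d.shot_var_per_count, d.cloud_fraction = 0.0, 0.0, 0.0
        model = CalibrationModel.from_distortions(d, known_constants=True)
        cal1 = calibrate_frame(render_frame(m1, camera, geom(), d, seed=3), model)
        cal2 = calibrate_frame(render_frame(scaled, camera, geom(), d, seed=3), model)
        both = cal1.valid & cal2.valid & (cal1.values[1] > 0.1)
        ratio = cal2.values[:, both] / cal1.values[:, both]
        assert np.abs(np.median(ratio) - 2.0) < 0.02

    def test_permuting_linearity_and_flatfield_worsens_round_trip(
        self, small_maps, camera
    ):
        # a low knee puts many pixels in the nonlinear regime, where the
        # order of the two corrections genuinely matters
        m1, _ = small_maps
        d = DistortionConfig()
        d.read_noise = d.shot_var_per_count = d.cloud_fraction = 0.0
        d.n_sources = 0
        d.knee_frac = 0.5
        model = CalibrationModel.from_distortions(d, known_constants=True)
        raw = render_frame(m1, camera, geom(), d, seed=9)
        truth = raw.truth["radiance"]

        def run(swap: bool):
            fr = decode(raw)
            fr.log["iso_ref"] = model.iso_ref
            fr.log["lens_transmittance"] = model.lens_transmittance
            if swap:
                fr = correct_linearity(correct_flatfield(fr, model), model)
            else:
                fr = correct_flatfield(correct_linearity(fr, model), model)
            fr = spectral_characterize(fr, model)
            fr = radiometric_correct(fr, model.instrumental_constants, model)
            fr = atmospheric_correct(fr, model)
            ok = fr.valid & (truth[1] > 0)
            return np.mean(np.abs(fr.values[:, ok] - truth[:, ok]) / truth[:, ok])

        assert run(swap=True) > 10 * run(swap=False)

    def test_no_negative_radiance_on_valid_pixels(self, distorted_raw, truth_model):
        cal = calibrate_frame(distorted_raw, truth_model)
        assert np.nanmin(cal.values[:, cal.valid]) >= 0.0
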