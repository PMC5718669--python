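import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctdose import (
    CalibrationPoint,
    FilmStrip,
    ScatterModelParams,
    build_calibration,
    default_grid,
    exposure_to_dose,
    extract_normalized_profile,
    generate_profile,
    measure_beam_width_fwhm,
    net_optical_density,
    pv_to_exposure,
    render_film_strip,
    roi_mean_red,
)
from cbctdose.profiles import DoseProfile

from conftest import make_log_calibration


def _strip_from_red(red, dpi=72.0):
    img = np.zeros(red.shape + (3,), dtype=np.uint16)
    img[..., 0] = red
    return FilmStrip(image=img, dpi=dpi, z_axis=1)


class TestRoiMean:
    def test_uniform_roi(self):
        strip = _strip_from_red(np.full((20, 30), 30000, dtype=np.uint16))
        assert roi_mean_red(strip, (0, 20, 0, 30)) == 30000.0

    def test_checkerboard_mean(self):
        red = np.zeros((10, 10), dtype=np.uint16)
        red[::2, ::2] = 65535
        red[1::2, 1::2] = 65535
        strip = _strip_from_red(red)
        assert roi_mean_red(strip, (0, 10, 0, 10)) == 65535 / 2

    def test_known_values_match_brute_force_sum(self):
        rng = np.random.default_rng(1)
        red = rng.integers(1000, 60000, size=(25, 20)).astype(np.uint16)
        strip = _strip_from_red(red)
        expected = red.astype(float).sum() / 500.0
        assert roi_mean_red(strip, (0, 25, 0, 20)) == pytest.approx(expected, rel=1e-12)

    def test_out_of_bounds_roi_refused(self):
        strip = _strip_from_red(np.ones((5, 5), dtype=np.uint16))
        with pytest.raises(ValueError):
            roi_mean_red(strip, (0, 6, 0, 5))
        with pytest.raises(ValueError):
            roi_mean_red(strip, (3, 3, 0, 5))


class TestNetOpticalDensity:
    @pytest.mark.parametrize(
        "pv, pv0, expected",
        [(40000, 40000, 0.0), (4000, 40000, 1.0), (20000, 40000, 0.30103)],
    )
    def test_reflective_density_values(self, pv, pv0, expected):
        assert net_optical_density(pv, pv0) == pytest.approx(expected, abs=1e-5)

    def test_negative_nod_flags_miscalibration(self):
        with pytest.raises(ValueError, match="negative NOD"):
            net_optical_density(41000, 40000)


class TestCalibration:
    def test_curve_passes_through_every_knot(self, log_calibration_curve):
        for p in log_calibration_curve.points:
            assert pv_to_exposure(log_calibration_curve, p.pixel_value) == pytest.approx(
                p.exposure_R, abs=1e-9
            )

    def test_unexposed_knot_maps_to_zero_roentgen(self, log_calibration_curve):
        assert pv_to_exposure(log_calibration_curve, 40000.0) == 0.0

    def test_cubic_reproduces_linear_data(self):
        pts = [CalibrationPoint(40000 - 2000 * i, float(i)) for i in range(6)]
        curve = build_calibration(pts)
        assert curve.exposure(39000.0) == pytest.approx(0.5, abs=1e-9)

    def test_withheld_midpoints_recovered_within_2_percent(self):
        """Generate-and-evaluate oracle: fit 10 points of a log response,
        check the withheld intermediate exposures."""
        pts = make_log_calibration(n=21)
        curve = build_calibration(pts[::2])
        for withheld in pts[1::2]:
            if withheld.exposure_R == 0:
                continue
            est = curve.exposure(withheld.pixel_value)
            assert est == pytest.approx(withheld.exposure_R, rel=0.02)

    def test_extrapolation_refused(self, log_calibration_curve):
        with pytest.raises(ValueError, match="extrapolation refused"):
            log_calibration_curve.exposure(50.0)
        with pytest.raises(ValueError, match="extrapolation refused"):
            log_calibration_curve.exposure(41000.0)

    def test_non_monotone_or_short_point_sets_refused(self):
        with pytest.raises(ValueError):
            build_calibration([(40000, 0.0), (41000, 1.0), (39000, 2.0)])
        with pytest.raises(ValueError):
            build_calibration([(40000, 0.0), (30000, 1.0)])
        with pytest.raises(ValueError):  # duplicate pv
            build_calibration([(40000, 0.0), (30000, 1.0), (30000, 2.0)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(st.floats(2100.0, 40000.0), st.floats(2100.0, 40000.0)))
    def test_pv_to_exposure_monotone_nonincreasing(self, pair):
        curve = build_calibration(make_log_calibration())
        lo, hi = sorted(pair)
        assert curve.exposure(lo) >= curve.exposure(hi)


class TestExposureToDose:
    def test_roentgen_to_rad_factor(self):
        assert exposure_to_dose(1.0) == 0.869
        assert exposure_to_dose(0.0) == 0.0
        assert exposure_to_dose(16.07) == pytest.approx(13.965, abs=5e-4)

    def test_negative_exposure_refused(self):
        with pytest.raises(ValueError):
            exposure_to_dose(-0.1)


class TestProfileExtraction:
    def test_pixel_pitch_from_dpi(self):
        strip = _strip_from_red(np.full((4, 10), 30000, dtype=np.uint16), dpi=72.0)
        assert strip.pixel_pitch_mm == pytest.approx(25.4 / 72, abs=1e-6)

    def test_rectangle_round_trip_recovers_unit_center(self, log_calibration_curve):
        z = default_grid(60.0, 0.5)
        dose = np.where(np.abs(z) < 20.0, 1.0, 0.05)
        profile = DoseProfile(z_mm=z, dose_cgy=dose)
        strip = render_film_strip(profile, log_calibration_curve, peak_dose_cgy=10.0)
        extracted = extract_normalized_profile(strip, log_calibration_curve)
        assert np.interp(0.0, extracted.z_mm, extracted.dose_cgy) == pytest.approx(
            1.0, abs=1e-6
        )
        core = np.abs(extracted.z_mm) < 15.0
        np.testing.assert_allclose(extracted.dose_cgy[core], 1.0, rtol=0.01)

    def test_synthetic_profile_round_trip_within_one_percent(self, log_calibration_curve):
        """Synthesis/analysis inverse pair: render a scatter-model profile
        through the inverted calibration, extract, compare."""
        params = ScatterModelParams(1.0, 0.4, 50.0, penumbra_sigma=2.0)
        profile = generate_profile(40.0, params, default_grid(200.0, 0.5))
        strip = render_film_strip(profile, log_calibration_curve, peak_dose_cgy=12.0)
        extracted = extract_normalized_profile(strip, log_calibration_curve)
        truth = np.interp(extracted.z_mm, profile.z_mm, profile.dose_cgy)
        truth /= np.interp(0.0, profile.z_mm, profile.dose_cgy)
        mask = truth > 0.05 * truth.max()
        np.testing.assert_allclose(
            extracted.dose_cgy[mask], truth[mask], rtol=0.01
        )

    def test_saturated_pixels_reported(self, log_calibration_curve):
        red = np.full((4, 30), 30000, dtype=np.uint16)
        red[:, 10] = 100  # darker than any calibration point
        strip = _strip_from_red(red)
        with pytest.raises(ValueError, match="z indices \\[10\\]"):
            extract_normalized_profile(strip, log_calibration_curve)

    def test_tiff_io_round_trip(self, tmp_path, log_calibration_curve):
        z = default_grid(40.0, 0.5)
        profile = DoseProfile(z_mm=z, dose_cgy=np.where(np.abs(z) < 10, 1.0, 0.1))
        strip = render_film_strip(profile, log_calibration_curve, peak_dose_cgy=5.0)
        path = strip.to_tiff(tmp_path / "strip.tif")
        back = FilmStrip.from_tiff(path, dpi=strip.dpi)
        assert np.array_equal(back.image, strip.image)


class TestFwhm:
    def test_rectangle_width(self):
        z = default_grid(60.0, 0.5)
        prof = DoseProfile(z_mm=z, dose_cgy=np.where(np.abs(z) < 10.0, 1.0, 0.0))
        assert measure_beam_width_fwhm(prof) == pytest.approx(20.0, abs=0.5)

    def test_blurred_rectangle_keeps_rect_width(self):
        """FWHM of rect * Gaussian equals the rect width when sigma << width."""
        params = ScatterModelParams(1.0, 0.0, 50.0, penumbra_sigma=1.0)
        prof = generate_profile(20.0, params, default_grid(200.0, 0.25))
        assert measure_beam_width_fwhm(prof) == pytest.approx(20.0, abs=0.1)

    def test_triangle_half_base(self):
        z = default_grid(40.0, 0.5)
        prof = DoseProfile(z_mm=z, dose_cgy=np.clip(1.0 - np.abs(z) / 20.0, 0.0, None))
        assert measure_beam_width_fwhm(prof) == pytest.approx(20.0, abs=1e-9)

    def test_profile_never_below_half_max_refused(self):
        z = default_grid(20.0, 0.5)
        prof = DoseProfile(z_mm=z, dose_cgy=np.full(z.shape, 1.0) + 0.1 * (z == 0))
        with pytest.raises(ValueError, match="half maximum"):
            measure_beam_width_fwhm(prof)
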