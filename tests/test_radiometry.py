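import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from litfield import (
    CameraCalibration,
    ExposureMeta,
    counts_to_radiance,
    energy_to_photon_radiance,
    ev_to_factor,
    from_lit,
    lit_span_to_factor,
    photon_energy_percent_diff,
    to_lit,
    vignetting_correct,
    white_from_rgb,
)
from litfield.radiometry import PLANCK_CONSTANT, SPEED_OF_LIGHT, VIGNETTING_THETA_GRID


class TestLitScale:
    @pytest.mark.parametrize(
        "radiance, lit", [(1e11, 11.0), (10 ** 16.5, 16.5), (1.0, 0.0)]
    )
    def test_log_definition(self, radiance, lit):
        assert to_lit(radiance) == pytest.approx(lit, abs=1e-12)

    def test_rejects_corrupt_input(self):
        with pytest.raises(ValueError):
            to_lit(np.array([1e10, np.nan]))
        with pytest.raises(ValueError):
            to_lit(-1.0)

    @given(st.floats(min_value=5, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, lit):
        radiance = from_lit(lit)
        assert abs(from_lit(to_lit(radiance)) - radiance) / radiance < 1e-12

    def test_small_span_is_2_3_percent(self):
        _, percent = lit_span_to_factor(0.01)
        assert round(percent, 1) == 2.3

    def test_two_lit_is_factor_100(self):
        factor, _ = lit_span_to_factor(2.0)
        assert factor == pytest.approx(100.0)
        assert lit_span_to_factor(0.0) == (1.0, 0.0)

    @given(
        st.floats(min_value=-3, max_value=3), st.floats(min_value=-3, max_value=3)
    )
    @settings(max_examples=50, deadline=None)
    def test_span_log_additivity(self, a, b):
        fa, _ = lit_span_to_factor(a)
        fb, _ = lit_span_to_factor(b)
        fab, _ = lit_span_to_factor(a + b)
        assert fab == pytest.approx(fa * fb, rel=1e-12)


class TestExposureArithmetic:
    @pytest.mark.parametrize("ev, factor", [(3, 8), (6, 64), (0, 1)])
    def test_ev_steps(self, ev, factor):
        assert ev_to_factor(ev) == factor


class TestPhotonArithmetic:
    def test_visible_spectrum_energy_spread(self):
        # hc/400nm is exactly 75% more energetic than hc/700nm
        assert photon_energy_percent_diff(400, 700) == pytest.approx(75.0)
        assert photon_energy_percent_diff(500, 500) == 0.0
        assert photon_energy_percent_diff(350, 700) == pytest.approx(100.0)

    def test_rejects_nonpositive_wavelength(self):
        with pytest.raises(ValueError):
            photon_energy_percent_diff(0, 700)

    def test_energy_conversion_against_direct_arithmetic(self):
        # independent oracle: λ/(hc) evaluated with the raw constants
        expected = 500e-9 / (PLANCK_CONSTANT * SPEED_OF_LIGHT)
        got = energy_to_photon_radiance(1.0, 500)
        assert got == pytest.approx(expected, rel=1e-12)
        assert to_lit(got) == pytest.approx(18.4, abs=0.001)
        assert energy_to_photon_radiance(0.0, 632.8) == 0.0
        assert energy_to_photon_radiance(2.0, 500) == pytest.approx(2 * got)


def _cal(k=1e12, black=0.0, white=16000.0, vignetting=None):
    v = np.ones(10) if vignetting is None else np.asarray(vignetting)
    return CameraCalibration(
        channel_scale={"red": k, "green": k, "blue": k},
        black_level=black,
        white_level=white,
        iso_gain={100.0: 1.0},
        aperture_gain={3.5: 1.0},
        vignetting={3.5: v},
        projection={},
    )


class TestCountsToRadiance:
    def test_hand_computed_fixture(self):
        cal = _cal(k=1e12, black=0.0)
        meta = ExposureMeta(exposure_time=0.01, iso=100, f_number=3.5)
        counts = np.full((4, 4, 3), 500.0)
        radiance, sat = counts_to_radiance(counts, meta, cal)
        assert np.allclose(radiance, 5e16)
        assert not sat.any()

    def test_black_level_maps_to_floor(self):
        cal = _cal(black=256.0)
        meta = ExposureMeta(exposure_time=1.0, iso=100, f_number=3.5)
        counts = np.full((2, 2, 3), 256.0)
        counts[0, 0] = 300.0
        radiance, _ = counts_to_radiance(counts, meta, cal)
        positive = (300 - 256) * 1e12
        assert radiance[0, 0, 0] == pytest.approx(positive)
        # clamped to 1e-3 x smallest positive value, never zero
        assert np.all(radiance > 0)
        assert radiance[1, 1, 0] == pytest.approx(1e-3 * positive)

    def test_exposure_reciprocity(self):
        cal = _cal()
        counts = np.random.default_rng(0).uniform(100, 1000, (3, 3, 3))
        r1, _ = counts_to_radiance(
            counts, ExposureMeta(exposure_time=0.01, iso=100, f_number=3.5), cal
        )
        r2, _ = counts_to_radiance(
            counts, ExposureMeta(exposure_time=0.02, iso=100, f_number=3.5), cal
        )
        assert np.allclose(r2, r1 / 2)

    @given(
        st.floats(min_value=1.0, max_value=15000.0),
        st.floats(min_value=1e-4, max_value=30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_property(self, count, t):
        cal = _cal()
        meta = ExposureMeta(exposure_time=t, iso=100, f_number=3.5)
        base, _ = counts_to_radiance(np.full((1, 1, 3), count), meta, cal)
        doubled, _ = counts_to_radiance(np.full((1, 1, 3), 2 * count), meta, cal)
        assert np.allclose(doubled, 2 * base, rtol=1e-12)

    def test_saturation_mask_threshold(self):
        cal = _cal(white=16000.0)
        meta = ExposureMeta(exposure_time=1.0, iso=100, f_number=3.5)
        counts = np.array([[[15000.0, 15841.0, 16000.0]]])
        _, sat = counts_to_radiance(counts, meta, cal)
        assert list(sat[0, 0]) == [False, True, True]  # threshold 0.99*white

    def test_missing_calibration_key_is_named(self):
        with pytest.raises(ValueError, match="blue"):
            CameraCalibration(
                channel_scale={"red": 1.0, "green": 1.0},
                black_level=0,
                white_level=1,
                iso_gain={},
                aperture_gain={},
                vignetting={},
            )


class TestVignetting:
    def test_unit_table_is_identity(self):
        cal = _cal()
        image = np.random.default_rng(1).uniform(1, 2, (5, 5, 3))
        theta = np.random.default_rng(2).uniform(0, 90, (5, 5))
        assert np.array_equal(vignetting_correct(image, theta, cal, 3.5), image)

    def test_linear_interpolation_between_table_points(self):
        table = np.ones(10)
        table[1] = 0.9
        cal = _cal(vignetting=table)
        out = vignetting_correct(np.ones((1, 1, 3)), np.array([[5.0]]), cal, 3.5)
        assert np.allclose(out, 1 / 0.95)

    @given(st.floats(min_value=0.3, max_value=1.0))
    @settings(max_examples=20, deadline=None)
    def test_apply_then_correct_round_trip(self, rim):
        # flat field x known V(theta), corrected back flat to <1%
        table = np.linspace(1.0, rim, 10)
        cal = _cal(vignetting=table)
        theta = np.linspace(0, 90, 50).reshape(5, 10)
        v = np.interp(theta, VIGNETTING_THETA_GRID, table)
        flat = np.ones((5, 10, 3))
        corrected = vignetting_correct(flat * v[..., None], theta, cal, 3.5)
        assert np.all(np.abs(corrected - 1.0) < 0.01)

    def test_geometry_bug_raises(self):
        cal = _cal()
        with pytest.raises(ValueError):
            vignetting_correct(np.ones((1, 1, 3)), np.array([[95.0]]), cal, 3.5)

    def test_unknown_aperture_falls_back_with_warning(self):
        cal = _cal()
        with pytest.warns(UserWarning):
            vignetting_correct(np.ones((1, 1, 3)), np.array([[10.0]]), cal, 8.0)


class TestWhiteFromRGB:
    def test_equal_bands(self):
        assert white_from_rgb(2.0, 2.0, 2.0) == 2.0
        assert white_from_rgb(0.0, 0.0, 3.0) == 1.0

    def test_log_of_equal_power_bands(self):
        assert to_lit(white_from_rgb(1e16, 1e16, 1e16)) == pytest.approx(16.0)

    def test_array_form_matches_scalar_form(self, rng):
        rgb = rng.uniform(1, 5, (4, 4, 3))
        assert np.allclose(
            white_from_rgb(rgb),
            white_from_rgb(rgb[..., 0], rgb[..., 1], rgb[..., 2]),
        )


class TestCalibrationFile:
    def test_json_round_trip(self, tmp_path, small_cal):
        path = tmp_path / "cal.json"
        small_cal.save(path)
        loaded = CameraCalibration.load(path)
        assert loaded.channel_scale == small_cal.channel_scale
        assert np.allclose(loaded.vignetting_for(3.5), small_cal.vignetting_for(3.5))
        assert loaded.projection == small_cal.projection

    def test_strict_validation(self, tmp_path, small_cal):
        d = small_cal.to_dict()
        del d["vignetting"]
        with pytest.raises(KeyError, match="vignetting"):
            CameraCalibration.from_dict(d)
        bad = small_cal.to_dict()
        bad["black_level"] = bad["white_level"] + 1
        with pytest.raises(ValueError):
            CameraCalibration.from_dict(bad)
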