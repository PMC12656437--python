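"""Flat-field correction, trimming, normalization, band lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperfod.calib import (
    CalibrationLibrary,
    compute_gain,
    flat_field_correct,
    nearest_band,
    normalize_pixelwise,
    preprocess,
    select_calibration,
    trim_bands,
)
from hyperfod.cube_io import CalibrationPair, Hypercube, default_wavelength_grid

from conftest import make_pair, make_raw_cube


class TestGain:
    def test_constant_flat_gives_unit_gain(self):
        dark = np.full((4, 224), 100.0)
        pair = CalibrationPair(dark=dark, flat=dark + 7.0)
        g = compute_gain(pair)
        assert g.m == pytest.approx(7.0)
        np.testing.assert_allclose(g.gain, 1.0)

    def test_two_element_toy(self):
        # F - D = [1, 3]  ->  m = 2, G = [0.5, 1.5]
        pair = CalibrationPair(dark=np.zeros((1, 2)), flat=np.array([[1.0, 3.0]]))
        g = compute_gain(pair)
        assert g.m == pytest.approx(2.0)
        np.testing.assert_allclose(g.gain, [[0.5, 1.5]])

    def test_mean_of_diff_over_gain_is_m(self, rng):
        pair = make_pair(rng)
        g = compute_gain(pair)
        np.testing.assert_allclose(((pair.flat - pair.dark) / g.gain).mean(), g.m)

    def test_nonpositive_diff_rejected_with_location(self):
        dark = np.full((3, 224), 100.0)
        flat = dark + 5.0
        flat[1, 7] = 99.0
        with pytest.raises(ValueError, match=r"column 1, band 7"):
            CalibrationPair(dark=dark, flat=flat)


class TestFlatFieldCorrection:
    def test_dark_input_maps_to_zero(self, rng, calib_pair):
        cube = make_raw_cube(rng, samples=32)
        # keep the dark frame exactly representable so I == D holds bitwise
        calib_pair.dark = calib_pair.dark.astype(np.float32).astype(np.float64)
        cube.data = np.broadcast_to(calib_pair.dark.astype(np.float32), cube.data.shape).copy()
        out = flat_field_correct(cube, calib_pair)
        np.testing.assert_allclose(out.data, 0.0)
        assert out.state == "corrected224"

    def test_flat_input_maps_to_constant_m(self, rng, calib_pair):
        cube = make_raw_cube(rng, samples=32)
        cube.data = np.broadcast_to(calib_pair.flat.astype(np.float32), cube.data.shape).copy()
        out = flat_field_correct(cube, calib_pair)
        m = compute_gain(calib_pair).m
        spread = (out.data.max() - out.data.min()) / out.data.mean()
        assert spread < 1e-6
        np.testing.assert_allclose(out.data, m, rtol=1e-6)

    def test_matches_per_pixel_recomputation(self, rng):
        """Independent per-pixel oracle of the correction formula."""
        for _ in range(10):
            cube = make_raw_cube(rng, lines=6, samples=9)
            pair = make_pair(rng, samples=9)
            out = flat_field_correct(cube, pair)
            diff = pair.flat - pair.dark
            m = diff.mean()
            oracle = np.empty_like(out.data, dtype=np.float64)
            for c in range(9):
                for b in range(224):
                    oracle[:, c, b] = (cube.data[:, c, b] - pair.dark[c, b]) * m / diff[c, b]
            oracle = np.maximum(oracle, 0)
            np.testing.assert_allclose(out.data, oracle, rtol=1e-6)

    def test_forward_model_inversion(self, rng):
        """Cube built as I = D + (F - D) * R / m corrects back to R exactly."""
        pair = make_pair(rng, samples=12)
        m = compute_gain(pair).m
        reflectance = rng.uniform(0.05, 0.95, size=(5, 12, 224))
        data = pair.dark[None] + (pair.flat - pair.dark)[None] * reflectance / m
        cube = Hypercube(
            data=data.astype(np.float64), wavelengths=default_wavelength_grid(), state="raw224"
        )
        out = flat_field_correct(cube, pair)
        np.testing.assert_allclose(out.data, reflectance, rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng, calib_pair):
        cube = make_raw_cube(rng, samples=16)
        with pytest.raises(ValueError, match="match"):
            flat_field_correct(cube, calib_pair)

    def test_removes_column_stripes(self, rng):
        """Multiplicative per-column stripe gains vanish after correction."""
        samples = 40
        dark = np.full((samples, 224), 100.0)
        sensitivity = np.full(224, 2000.0)
        stripes = np.exp(rng.normal(0, 0.05, samples))
        flat = dark + stripes[:, None] * sensitivity[None, :]
        pair = CalibrationPair(dark=dark, flat=flat)
        reflectance = 0.6  # uniform target
        data = dark[None] + stripes[None, :, None] * sensitivity[None, None, :] * reflectance
        cube = Hypercube(
            data=np.repeat(data, 30, axis=0).astype(np.float32),
            wavelengths=default_wavelength_grid(),
            state="raw224",
        )
        before_cv = cube.data.mean(axis=(0, 2)).std() / cube.data.mean()
        out = flat_field_correct(cube, pair)
        col_means = out.data.mean(axis=(0, 2))
        after_cv = col_means.std() / col_means.mean()
        assert before_cv > 0.01
        assert after_cv < 1e-6


class TestTrim:
    def test_keeps_bands_20_to_203(self, rng, calib_pair):
        cube = flat_field_correct(make_raw_cube(rng), calib_pair)
        out = trim_bands(cube)
        assert out.n_bands == 184
        assert out.state == "trimmed184"
        np.testing.assert_array_equal(out.data, cube.data[:, :, 20:204])
        assert out.wavelengths[0] == pytest.approx(1012.045, abs=0.01)
        assert out.wavelengths[-1] == pytest.approx(default_wavelength_grid()[203])

    def test_trim_twice_is_an_error(self, rng, calib_pair):
        out = trim_bands(flat_field_correct(make_raw_cube(rng), calib_pair))
        with pytest.raises(ValueError, match="state"):
            trim_bands(out)


def _trimmed_cube(data):
    return Hypercube(
        data=np.asarray(data, dtype=np.float32),
        wavelengths=default_wavelength_grid()[20:204],
        state="trimmed184",
    )


class TestNormalization:
    def test_simple_spectrum(self):
        data = np.zeros((1, 1, 184), dtype=np.float32)
        data[0, 0, :3] = [2, 4, 6]
        data[0, 0, 3:] = 6.0
        out = normalize_pixelwise(_trimmed_cube(data), mode="minmax")
        np.testing.assert_allclose(out.data[0, 0, :3], [0, 0.5, 1])

    def test_minmax_attains_zero_and_one(self, rng):
        cube = _trimmed_cube(rng.uniform(10, 500, (4, 5, 184)))
        out = normalize_pixelwise(cube)
        assert out.state == "normalized184"
        np.testing.assert_allclose(out.data.min(axis=2), 0.0)
        np.testing.assert_allclose(out.data.max(axis=2), 1.0)

    @given(
        gain=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_minmax_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(99)
        base = rng.uniform(1, 300, (2, 3, 184))
        a = normalize_pixelwise(_trimmed_cube(base)).data
        b = normalize_pixelwise(_trimmed_cube(gain * base + offset)).data
        np.testing.assert_allclose(a, b, atol=2e-6)

    def test_minmax_exact_under_power_of_two_gain(self, rng):
        base = rng.uniform(1, 300, (2, 3, 184)).astype(np.float32)
        a = normalize_pixelwise(_trimmed_cube(base)).data
        b = normalize_pixelwise(_trimmed_cube(base * 8.0)).data
        np.testing.assert_array_equal(a, b)

    def test_max_gain_invariance_only(self, rng):
        base = rng.uniform(10, 300, (2, 3, 184))
        a = normalize_pixelwise(_trimmed_cube(base), mode="max").data
        b = normalize_pixelwise(_trimmed_cube(3.7 * base), mode="max").data
        c = normalize_pixelwise(_trimmed_cube(base + 40.0), mode="max").data
        np.testing.assert_allclose(a, b, atol=2e-6)
        assert np.abs(a - c).max() > 1e-3  # offsets do NOT cancel in this mode
        assert a.min() >= 0 and a.max() <= 1

    def test_constant_spectrum_goes_to_zero(self, caplog):
        data = np.full((1, 2, 184), 5.0, dtype=np.float32)
        with caplog.at_level("WARNING"):
            out = normalize_pixelwise(_trimmed_cube(data))
        np.testing.assert_array_equal(out.data, 0.0)
        assert "degenerate" in caplog.text


class TestNearestBand:
    def test_rule_wavelengths_resolve_on_trimmed_grid(self):
        cube = _trimmed_cube(np.ones((1, 1, 184)))
        assert nearest_band(cube, 1012.0) == 0
        # neighbouring rule wavelengths resolve to distinct bands
        bands = [nearest_band(cube, w) for w in (1211.5, 1215.0, 1222.0, 1225.5, 1232.5, 1407.5, 1411.0)]
        assert len(set(bands)) == len(bands)

    def test_exact_grid_value_is_identity(self):
        cube = _trimmed_cube(np.ones((1, 1, 184)))
        for idx in (0, 50, 183):
            assert nearest_band(cube, float(cube.wavelengths[idx])) == idx

    def test_out_of_range_rejected(self):
        cube = _trimmed_cube(np.ones((1, 1, 184)))
        with pytest.raises(ValueError, match="outside"):
            nearest_band(cube, 942.0)


class TestSelectCalibration:
    def _library(self, rng, temps):
        pairs = []
        for t in temps:
            p = make_pair(rng)
            p.temperature = t
            pairs.append(p)
        return CalibrationLibrary(pairs=pairs)

    def test_nearest_and_tie_break(self, rng):
        lib = self._library(rng, [10.0, 48.0])
        assert select_calibration(lib, 45.0).temperature == 48.0
        assert select_calibration(lib, 10.0).temperature == 10.0
        # 29 degC is 19 away from both; tie goes to the lower temperature
        assert select_calibration(lib, 29.0).temperature == 10.0

    def test_empty_library(self):
        with pytest.raises(ValueError, match="empty"):
            select_calibration(CalibrationLibrary(pairs=[]), 25.0)

    def test_duplicate_temperatures_rejected(self, rng):
        with pytest.raises(ValueError, match="unique"):
            self._library(rng, [20.0, 20.0])


def test_preprocess_chain_states(rng, calib_pair):
    out = preprocess(make_raw_cube(rng), calib_pair)
    assert out.state == "normalized184"
    assert out.n_bands == 184
    assert out.data.min() >= 0 and out.data.max() <= 1
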