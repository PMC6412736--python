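"""Pre-processing chain: calibration closed forms, denoising, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hsibrain.hsio import RawCube, ReferencePair
from hsibrain.preprocess import (
    CalibratedCube,
    CalibrationError,
    calibrate,
    denoise,
    normalize,
    preprocess_chain,
)
from tests.conftest import make_refs


def cube_of(data, wl=None):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[2], dtype=float) + 400 if wl is None else wl
    return RawCube(data, wl)


class TestCalibrate:
    shape = (3, 4, 5)

    def test_raw_equals_white_gives_100(self):
        refs = make_refs(self.shape)
        out = calibrate(cube_of(refs.white), refs)
        np.testing.assert_allclose(out.data, 100.0)

    def test_raw_equals_dark_gives_0(self):
        refs = make_refs(self.shape)
        out = calibrate(cube_of(refs.dark), refs)
        np.testing.assert_allclose(out.data, 0.0)

    def test_quarter_point_gives_25(self):
        refs = make_refs(self.shape)
        raw = refs.dark + 0.25 * (refs.white - refs.dark)
        np.testing.assert_allclose(calibrate(cube_of(raw), refs).data, 25.0)

    def test_affine_in_raw_signal(self):
        """calibrate(a*R1 + b*R2) relates linearly to the calibrations of R1, R2."""
        rng = np.random.default_rng(0)
        refs = make_refs(self.shape)
        r1 = rng.uniform(60, 190, self.shape)
        r2 = rng.uniform(60, 190, self.shape)
        lhs = calibrate(cube_of(0.3 * r1 + 0.7 * r2), refs).data
        rhs = (
            0.3 * calibrate(cube_of(r1), refs).data
            + 0.7 * calibrate(cube_of(r2), refs).data
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_nonpositive_reference_span_is_error_naming_location(self):
        refs = make_refs(self.shape)
        refs.white[1, 2, 3] = refs.dark[1, 2, 3]
        with pytest.raises(CalibrationError, match=r"\(1, 2\), band 3"):
            calibrate(cube_of(refs.dark), refs)


class TestDenoise:
    def test_826_bands_reduce_to_128_within_operating_range(self):
        wl = np.linspace(400, 1000, 826)
        cal = CalibratedCube(np.random.default_rng(0).uniform(0, 100, (4, 4, 826)), wl)
        out = denoise(cal)
        assert out.data.shape == (4, 4, 128)
        assert out.wavelengths[0] >= 450 and out.wavelengths[-1] <= 900
        assert (np.diff(out.wavelengths) > 0).all()

    def test_constant_spectrum_preserved(self):
        wl = np.linspace(400, 1000, 826)
        cal = CalibratedCube(np.full((2, 2, 826), 37.5), wl)
        np.testing.assert_allclose(denoise(cal).data, 37.5)

    def test_impulse_attenuated_to_moving_average_oracle(self):
        """A single-band impulse smooths exactly like a reflective moving average."""
        wl = np.arange(400.0, 430.0)
        spec = np.zeros(30)
        spec[13] = 8.0
        cal = CalibratedCube(np.tile(spec, (1, 1, 1)), wl)
        out = denoise(cal, smooth_window=5, band_low_nm=400, band_high_nm=429, out_bands=30)
        padded = np.r_[spec[2:0:-1], spec, spec[-2:-4:-1]]
        oracle = np.convolve(padded, np.ones(5) / 5, mode="valid")
        np.testing.assert_allclose(out.data[0, 0], oracle, atol=1e-12)
        assert out.data.max() < 8.0

    def test_commutes_with_spatial_crop(self):
        wl = np.linspace(400, 1000, 100)
        data = np.random.default_rng(1).uniform(0, 100, (6, 6, 100))
        cal = CalibratedCube(data, wl)
        full = denoise(cal, out_bands=16).data[:3, 1:4]
        cropped = denoise(CalibratedCube(data[:3, 1:4], wl), out_bands=16).data
        np.testing.assert_allclose(full, cropped)

    def test_too_many_output_bands_is_error(self):
        wl = np.linspace(400, 1000, 50)
        cal = CalibratedCube(np.zeros((2, 2, 50)), wl)
        with pytest.raises(ValueError, match="out_bands"):
            denoise(cal, out_bands=49)


class TestNormalize:
    def test_closed_form(self):
        cal = CalibratedCube(np.array([[[0.2, 0.6, 1.0]]]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(normalize(cal).data[0, 0], [0.0, 0.5, 1.0])

    def test_output_range_and_extrema(self):
        rng = np.random.default_rng(2)
        cal = CalibratedCube(rng.uniform(0, 100, (5, 5, 20)), np.arange(20.0))
        out = normalize(cal)
        np.testing.assert_allclose(out.data.min(axis=2), 0.0)
        np.testing.assert_allclose(out.data.max(axis=2), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        spec=hnp.arrays(
            np.float64,
            12,
            elements=st.floats(0, 100, allow_nan=False, width=32),
        ).filter(lambda s: s.max() - s.min() > 1e-6),
        scale=st.floats(0.1, 50),
        offset=st.floats(-20, 20),
    )
    def test_affine_invariance(self, spec, scale, offset):
        wl = np.arange(12.0)
        base = normalize(CalibratedCube(spec.reshape(1, 1, -1), wl)).data
        moved = normalize(
            CalibratedCube((scale * spec + offset).reshape(1, 1, -1), wl)
        ).data
        np.testing.assert_allclose(base, moved, atol=1e-7)

    def test_degenerate_pixel_zeroed_and_flagged(self):
        data = np.stack([np.full(6, 3.0), np.arange(6.0)]).reshape(2, 1, 6)
        out = normalize(CalibratedCube(data, np.arange(6.0)))
        assert out.degenerate_mask[0, 0] and not out.degenerate_mask[1, 0]
        np.testing.assert_array_equal(out.data[0, 0], 0.0)


class TestChain:
    def test_zero_noise_scene_recovers_normalized_signature(self, clean_scene):
        out = preprocess_chain(clean_scene.cube, clean_scene.refs)
        truth = clean_scene.truth.labels
        wl = clean_scene.cube.wavelengths
        for c, sig in clean_scene.signatures.items():
            r, col = np.argwhere(truth == c)[0]
            cal = CalibratedCube(100.0 * sig.reshape(1, 1, -1), wl)
            expected = normalize(denoise(cal)).data[0, 0]
            np.testing.assert_allclose(out.data[r, col], expected, atol=1e-9)

    def test_output_has_128_bands(self, processed_cube):
        assert processed_cube.n_bands == 128

    def test_normalize_idempotent(self, processed_cube):
        again = normalize(
            CalibratedCube(processed_cube.data, processed_cube.band_wavelengths)
        )
        np.testing.assert_allclose(again.data, processed_cube.data, atol=1e-12)
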