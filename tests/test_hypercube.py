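"""ENVI I/O, black/white calibration, ROI spectra and wavelength trimming."""

import numpy as np
import pytest

from bananachem import (
    HyperCube, ROI, SpectraDataset, Spectrum, calibrate, read_envi,
    roi_mean_spectrum, trim_wavelengths, write_envi,
)
from bananachem.exceptions import CalibrationError, ConfigurationError, EnviFormatError


def _cube(rows=8, cols=8, bands=5, seed=0, dtype=np.float64):
    rng = np.random.default_rng(seed)
    data = (1000 * rng.random((rows, cols, bands))).astype(dtype)
    wl = np.linspace(400, 1000, bands)
    return HyperCube(data=data, wavelengths=wl, kind="raw")


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float64, np.float32, np.uint16])
    def test_round_trip_exact(self, tmp_path, interleave, dtype):
        cube = _cube(dtype=dtype)
        hdr = write_envi(cube, tmp_path / "cube", interleave=interleave)
        back = read_envi(hdr)
        assert np.array_equal(back.data, cube.data)
        assert np.allclose(back.wavelengths, cube.wavelengths)

    def test_interleaves_agree_with_loop_oracle(self, tmp_path):
        """De-interleaving matches an explicit triple loop on a 2x2x3 cube."""
        cube = _cube(rows=2, cols=2, bands=3, seed=3)
        flat = {}
        for interleave in ("bsq", "bil", "bip"):
            hdr = write_envi(cube, tmp_path / interleave, interleave=interleave)
            flat[interleave] = np.fromfile(hdr.with_suffix(".img"), dtype=np.float64)
        oracle = np.zeros((2, 2, 3))
        # BSQ stores band-major: value(b, r, c) at index b*R*C + r*C + c
        for b in range(3):
            for r in range(2):
                for c in range(2):
                    oracle[r, c, b] = flat["bsq"][b * 4 + r * 2 + c]
        assert np.array_equal(oracle, cube.data)
        for interleave in ("bil", "bip"):
            assert np.array_equal(read_envi(tmp_path / f"{interleave}.hdr").data,
                                  cube.data)

    def test_band_count_mismatch_is_format_error(self, tmp_path):
        hdr = write_envi(_cube(bands=4), tmp_path / "bad")
        text = hdr.read_text().replace("bands = 4", "bands = 3")
        text = text.replace(
            "wavelength = {", "wavelength = { 1, 2, 3 }\nignored = {")
        hdr.write_text(text)
        with pytest.raises(EnviFormatError, match="size"):
            read_envi(hdr)

    def test_missing_wavelengths_is_format_error(self, tmp_path):
        hdr = write_envi(_cube(), tmp_path / "nowl")
        lines = [l for l in hdr.read_text().splitlines() if not l.startswith("wavelength =")]
        hdr.write_text("\n".join(lines))
        with pytest.raises(EnviFormatError, match="wavelength"):
            read_envi(hdr)

    def test_unsupported_interleave_named(self, tmp_path):
        hdr = write_envi(_cube(), tmp_path / "weird")
        hdr.write_text(hdr.read_text().replace("interleave = bsq", "interleave = bsx"))
        with pytest.raises(EnviFormatError, match="bsx"):
            read_envi(hdr)


class TestCalibrate:
    def test_raw_equal_white_gives_one_and_dark_gives_zero(self):
        wl = np.linspace(400, 1000, 4)
        dark = np.full((6, 4), 100.0)
        white = np.full((6, 4), 900.0)
        ones = calibrate(HyperCube(np.broadcast_to(white, (5, 6, 4)).copy(), wl), dark, white)
        zeros = calibrate(HyperCube(np.broadcast_to(dark, (5, 6, 4)).copy(), wl), dark, white)
        assert np.allclose(ones.data, 1.0)
        assert np.allclose(zeros.data, 0.0)
        assert ones.kind == "reflectance"

    def test_hand_value(self):
        wl = np.array([500.0])
        raw = HyperCube(np.full((2, 2, 1), 60.0), wl)
        r = calibrate(raw, np.full((2, 1), 20.0), np.full((2, 1), 100.0))
        assert np.allclose(r.data, 0.5)

    def test_affine_invariance_under_common_scaling(self, rng):
        raw = _cube(5, 6, 3, seed=1)
        dark = 10 + 5 * rng.random((6, 3))
        white = 2000 + 100 * rng.random((6, 3))
        r1 = calibrate(raw, dark, white)
        scaled = HyperCube(raw.data * 3.7, raw.wavelengths, "raw")
        r2 = calibrate(scaled, dark * 3.7, white * 3.7)
        assert np.allclose(r1.data, r2.data, atol=1e-9)

    def test_full_cube_references_are_row_averaged(self):
        raw = _cube(4, 3, 2, seed=2)
        raw.data *= 0.4  # keep ratios inside the reflectance sanity range
        dark = np.zeros((4, 3, 2))
        white = np.full((4, 3, 2), 500.0)
        white[0] = 300.0  # rows average to (300 + 3*500)/4 = 450
        r = calibrate(raw, dark, white)
        assert np.allclose(r.data, raw.data / 450.0)

    def test_white_not_above_dark_is_calibration_error(self):
        raw = _cube(4, 4, 2)
        dark = np.full((4, 2), 50.0)
        white = np.full((4, 2), 50.0)
        with pytest.raises(CalibrationError, match="band"):
            calibrate(raw, dark, white)


class TestRoiMeanSpectrum:
    def _reflectance(self):
        rng = np.random.default_rng(4)
        return HyperCube(rng.random((6, 6, 3)), np.array([400.0, 500, 600]),
                         kind="reflectance")

    def test_singleton_roi_returns_pixel(self):
        cube = self._reflectance()
        spec = roi_mean_spectrum(cube, ROI(rect=(2, 3, 3, 4)), "s1")
        assert np.array_equal(spec.values, cube.data[2, 3])
        assert spec.sample_id == "s1"

    def test_two_pixel_mean(self):
        cube = self._reflectance()
        cube.data[0, 0] = 0.2
        cube.data[0, 1] = 0.4
        spec = roi_mean_spectrum(cube, ROI(rect=(0, 0, 1, 2)))
        assert np.allclose(spec.values, 0.3)

    def test_full_frame_on_constant_cube(self):
        cube = HyperCube(np.full((5, 5, 2), 0.77), np.array([400.0, 500]),
                         kind="reflectance")
        spec = roi_mean_spectrum(cube, ROI(rect=(0, 0, 5, 5)))
        assert np.allclose(spec.values, 0.77)

    def test_mask_roi_and_empty_roi(self):
        cube = self._reflectance()
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        spec = roi_mean_spectrum(cube, ROI(mask=mask))
        assert np.allclose(spec.values, (cube.data[1, 1] + cube.data[2, 2]) / 2)
        with pytest.raises(ConfigurationError, match="empty"):
            roi_mean_spectrum(cube, ROI(mask=np.zeros((6, 6), dtype=bool)))

    def test_roi_json_round_trip(self, tmp_path):
        roi = ROI(rect=(1, 2, 3, 4))
        roi.to_json(tmp_path / "roi.json")
        assert ROI.from_json(tmp_path / "roi.json").rect == (1, 2, 3, 4)


class TestTrimWavelengths:
    def test_closed_interval_boundaries(self):
        spec = Spectrum(np.array([390.0, 400, 700, 1000, 1005]), np.arange(5.0))
        out = trim_wavelengths(spec, 400, 1000)
        assert np.array_equal(out.wavelengths, [400, 700, 1000])
        assert np.array_equal(out.values, [1, 2, 3])

    def test_full_range_is_identity_and_idempotent(self, small_dataset):
        ds = small_dataset
        once = trim_wavelengths(ds, 400, 1000)
        twice = trim_wavelengths(once, 400, 1000)
        assert np.array_equal(once.X, ds.X)
        assert np.array_equal(twice.X, once.X)
        assert np.array_equal(twice.wavelengths, once.wavelengths)

    def test_no_surviving_bands_raises(self, small_dataset):
        with pytest.raises(ConfigurationError, match="no bands"):
            trim_wavelengths(small_dataset, 1100, 1200)

    def test_dataset_trim_preserves_targets(self, scaled_data):
        ds, _ = scaled_data
        out = trim_wavelengths(ds, 500, 900)
        assert out.X.shape[1] == np.sum((ds.wavelengths >= 500) & (ds.wavelengths <= 900))
        assert np.array_equal(out.y_ssc, ds.y_ssc)
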