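"""Calibration, resampling, band trimming, stitching, and SNV contracts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unmixlabel.errors import (
    BandGridError,
    CalibrationError,
    DegenerateSpectrumError,
    EmptyBandRangeError,
    ShapeMismatchError,
)
from unmixlabel.hypercube import CalibrationFrames, Hypercube, Spectrum
from unmixlabel.phantom import nir_wavelengths, vis_wavelengths
from unmixlabel.preprocess import (
    calibrate_reflectance,
    preprocess_pipeline,
    resample_to_common_grid,
    snv_normalize,
    snv_normalize_cube,
    stitch_cubes,
    stitch_spectra,
    trim_bands,
)

from .conftest import toy_cube, toy_refs


class TestCalibration:
    @pytest.mark.parametrize("level,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 0.5)])
    def test_flat_field_identities(self, level, expected):
        """raw = dark + level*(white-dark) calibrates to `level` exactly."""
        refs = toy_refs((4, 4, 6))
        raw_data = refs.dark + level * (refs.white - refs.dark)
        raw = Hypercube(raw_data, 400.0 + np.arange(6), "VIS")
        out = calibrate_reflectance(raw, refs)
        assert np.array_equal(out.data, np.full((4, 4, 6), expected))

    def test_degenerate_white_rejected(self):
        raw = toy_cube(4, 4, 6)
        refs = CalibrationFrames(np.full((4, 4, 6), 0.1), np.full((4, 4, 6), 0.1))
        with pytest.raises(CalibrationError):
            calibrate_reflectance(raw, refs)

    def test_shape_mismatch_rejected(self):
        raw = toy_cube(4, 4, 6)
        with pytest.raises(ShapeMismatchError):
            calibrate_reflectance(raw, toy_refs((4, 4, 7)))


class TestResample:
    def test_shape_and_pitch_contract(self):
        vis = toy_cube(64, 48, 3, camera="VIS", pitch=0.16)
        nir = toy_cube(32, 24, 3, camera="NIR", pitch=0.5)
        v, n = resample_to_common_grid(vis, nir, 32, 24, 0.5)
        assert v.data.shape == (32, 24, 3) and n.data.shape == (32, 24, 3)
        assert v.pixel_pitch == n.pixel_pitch == 0.5
        assert np.array_equal(v.wavelengths, vis.wavelengths)

    def test_identity_when_already_on_grid(self):
        nir = toy_cube(32, 24, 3, camera="NIR")
        _, out = resample_to_common_grid(toy_cube(32, 24, 3), nir, 32, 24, 0.5)
        assert np.array_equal(out.data, nir.data)

    def test_bright_pixel_maps_to_scaled_location(self):
        """Oracle: direct coordinate mapping of the affine scale."""
        data = np.zeros((120, 90, 2))
        data[80, 30] = 1.0
        cube = Hypercube(data, np.array([500.0, 600.0]), "VIS", 0.16)
        out, _ = resample_to_common_grid(cube, toy_cube(30, 30, 2), 40, 30, 0.5)
        r, c = np.unravel_index(np.argmax(out.data[:, :, 0]), (40, 30))
        # center-aligned mapping: out coord = (in + 0.5) * scale - 0.5
        assert abs(r - (80.5 * 40 / 120 - 0.5)) <= 1
        assert abs(c - (30.5 * 30 / 90 - 0.5)) <= 1

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            resample_to_common_grid(toy_cube(), toy_cube(), 0, 10, 0.5)


class TestTrimBands:
    def test_clinical_band_counts(self):
        """Trimming the phantom grids leaves 318 VIS + 210 NIR bands."""
        vis = Hypercube(np.zeros((2, 2, 328)), vis_wavelengths(full=True), "VIS")
        nir = Hypercube(np.zeros((2, 2, 220)), nir_wavelengths(full=True), "NIR")
        assert trim_bands(vis, 450.0, 951.0).n_bands == 318
        assert trim_bands(nir, 954.0, 1650.0).n_bands == 210

    def test_covering_range_is_identity_and_idempotent(self):
        cube = toy_cube(3, 3, 10)
        once = trim_bands(cube, 390.0, 450.0)
        assert once.n_bands == cube.n_bands
        twice = trim_bands(once, 390.0, 450.0)
        assert np.array_equal(once.data, twice.data)

    def test_empty_range_rejected(self):
        with pytest.raises(EmptyBandRangeError):
            trim_bands(toy_cube(3, 3, 10), 2000.0, 2100.0)


class TestStitch:
    def test_offset_rule_and_junction_continuity(self):
        vis = Spectrum(np.array([0.2, 0.5]), np.array([948.0, 951.0]))
        nir = Spectrum(np.array([0.3, 0.4]), np.array([954.0, 959.0]))
        out = stitch_spectra(vis, nir)
        # offset +0.2 applied to every NIR band; junction pair equal in value
        assert np.allclose(out.values, [0.2, 0.5, 0.5, 0.6])
        assert out.values[2] - out.values[1] == 0.0

    def test_zero_offset_leaves_nir_unchanged(self):
        vis = Spectrum(np.array([0.1, 0.3]), np.array([948.0, 951.0]))
        nir = Spectrum(np.array([0.3, 0.7]), np.array([954.0, 959.0]))
        out = stitch_spectra(vis, nir)
        assert np.allclose(out.values[2:], [0.3, 0.7])

    def test_528_band_output(self):
        vis = Spectrum(np.zeros(318), vis_wavelengths())
        nir = Spectrum(np.ones(210), nir_wavelengths())
        assert len(stitch_spectra(vis, nir)) == 528

    def test_overlapping_ranges_rejected(self):
        vis = Spectrum(np.zeros(3), np.array([940.0, 950.0, 960.0]))
        nir = Spectrum(np.zeros(3), np.array([954.0, 959.0, 964.0]))
        with pytest.raises(BandGridError):
            stitch_spectra(vis, nir)

    def test_cube_stitching_is_per_pixel(self):
        rng = np.random.default_rng(3)
        vis = Hypercube(rng.uniform(0, 1, (4, 4, 3)), np.array([945.0, 948.0, 951.0]), "VIS")
        nir = Hypercube(rng.uniform(0, 1, (4, 4, 2)), np.array([954.0, 959.0]), "NIR")
        out = stitch_cubes(vis, nir)
        assert np.allclose(out.data[:, :, 3], vis.data[:, :, 2])  # pinned junction
        assert out.camera == "STITCHED"


class TestSNV:
    def test_mean_zero_sd_one(self):
        out = snv_normalize(Spectrum(np.array([1.0, 2.0, 4.0, 9.0]), np.arange(4.0)))
        assert abs(out.values.mean()) < 1e-12
        assert abs(out.values.std(ddof=1) - 1.0) < 1e-12

    def test_two_point_sample_sd_example(self):
        out = snv_normalize(Spectrum(np.array([1.0, 3.0]), np.array([1.0, 2.0])))
        assert np.allclose(out.values, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        """SNV(a*x + b) = SNV(x) for a > 0."""
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        wl = np.arange(5.0)
        base = snv_normalize(Spectrum(x, wl))
        trans = snv_normalize(Spectrum(scale * x + shift, wl))
        assert np.allclose(base.values, trans.values, atol=1e-9)

    def test_idempotence(self):
        x = Spectrum(np.array([0.3, 0.1, 0.7, 0.2]), np.arange(4.0))
        once = snv_normalize(x)
        twice = snv_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            snv_normalize(Spectrum(np.full(6, 0.4), np.arange(6.0)))

    def test_cube_snv_matches_per_spectrum(self):
        cube = toy_cube(3, 2, 9)
        out = snv_normalize_cube(cube)
        one = snv_normalize(cube.spectrum_at(1, 1))
        assert np.allclose(out.data[1, 1], one.values)


class TestPipeline:
    def test_phantom_shape_and_snv_contract(self, noiseless_scene):
        cube = preprocess_pipeline(
            noiseless_scene.vis_raw,
            noiseless_scene.nir_raw,
            noiseless_scene.refs_vis,
            noiseless_scene.refs_nir,
        )
        cfg = noiseless_scene.config
        assert cube.data.shape == (cfg.rows, cfg.cols, 528)
        assert cube.camera == "STITCHED"
        assert np.abs(cube.data.mean(axis=2)).max() < 1e-9
        assert np.abs(cube.data.std(axis=2, ddof=1) - 1).max() < 1e-9

    def test_matches_stagewise_hand_application(self, noiseless_scene):
        """Pipeline equals calibrate/trim/stitch/SNV applied by hand to a pixel."""
        sc = noiseless_scene
        cube = preprocess_pipeline(sc.vis_raw, sc.nir_raw, sc.refs_vis, sc.refs_nir)
        r, c = 7, 21
        vis = (sc.vis_raw.data[r, c] - sc.refs_vis.dark[r, c]) / (
            sc.refs_vis.white[r, c] - sc.refs_vis.dark[r, c]
        )
        nir = (sc.nir_raw.data[r, c] - sc.refs_nir.dark[r, c]) / (
            sc.refs_nir.white[r, c] - sc.refs_nir.dark[r, c]
        )
        vis = vis[(sc.vis_raw.wavelengths >= 450) & (sc.vis_raw.wavelengths <= 951)]
        nir = nir[(sc.nir_raw.wavelengths >= 954) & (sc.nir_raw.wavelengths <= 1650)]
        spec = np.concatenate([vis, nir + (vis[-1] - nir[0])])
        spec = (spec - spec.mean()) / spec.std(ddof=1)
        assert np.allclose(cube.data[r, c], spec, atol=1e-10)
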