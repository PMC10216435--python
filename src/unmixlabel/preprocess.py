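"""Raw two-camera cubes -> one calibrated, stitched, SNV-normalized cube.

The processing chain, in order: flat-field calibration, spatial resampling
to a common grid, trimming of the low-sensitivity extremity bands, per-pixel
stitching of the VIS and NIR spectra at the 951/954 nm junction, and
standard normal variate (SNV) normalization of every pixel spectrum.

SNV subtracts the per-spectrum mean and divides by the per-spectrum sample
standard deviation, removing multiplicative surface-reflection and
tissue-curvature effects. It is applied last.
"""
from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import (
    BandGridError,
    CalibrationError,
    DegenerateSpectrumError,
    EmptyBandRangeError,
    ShapeMismatchError,
)
from .hypercube import CalibrationFrames, Hypercube, Spectrum

#: Retained wavelength windows after trimming the sensor extremities (nm).
VIS_BAND_RANGE = (450.0, 951.0)
NIR_BAND_RANGE = (954.0, 1650.0)


def calibrate_reflectance(raw: Hypercube, refs: CalibrationFrames) -> Hypercube:
    """Convert raw intensity counts to calibrated diffuse reflectance.

    Standard flat-field correction: ``(raw - dark) / (white - dark)``,
    element-wise per pixel and band. A white reference measures the
    illumination spectrum; the dark frame measures sensor dark current.
    """
    if refs.white.shape != raw.data.shape:
        raise ShapeMismatchError(
            f"calibration frames {refs.white.shape} do not match raw cube {raw.data.shape}"
        )
    denom = refs.white - refs.dark
    if np.any(denom <= 0):
        raise CalibrationError("white frame must exceed dark frame on every band used")
    reflectance = (raw.data - refs.dark) / denom
    return Hypercube(reflectance, raw.wavelengths.copy(), raw.camera, raw.pixel_pitch)


def resample_to_common_grid(
    vis: Hypercube,
    nir: Hypercube,
    target_rows: int,
    target_cols: int,
    target_pitch: float,
) -> tuple[Hypercube, Hypercube]:
    """Resample both cubes to a shared spatial grid.

    Band axes are untouched. Bilinear interpolation (with a Gaussian
    anti-aliasing prefilter when downscaling) maps each camera's spatial
    grid onto ``target_rows x target_cols`` at ``target_pitch`` mm/pixel.
    A cube already on the target grid is passed through unchanged.
    """
    if target_rows <= 0 or target_cols <= 0:
        raise ValueError("target shape must be positive")
    if target_pitch <= 0:
        raise ValueError("target pitch must be > 0")
    return (
        _resample_cube(vis, target_rows, target_cols, target_pitch),
        _resample_cube(nir, target_rows, target_cols, target_pitch),
    )


def _resample_cube(cube: Hypercube, rows: int, cols: int, pitch: float) -> Hypercube:
    if (cube.rows, cube.cols) == (rows, cols):
        return Hypercube(cube.data.copy(), cube.wavelengths.copy(), cube.camera, pitch)
    data = _sk_resize(
        cube.data,
        (rows, cols, cube.n_bands),
        order=1,
        mode="edge",
        anti_aliasing=None,  # prefilter only when downscaling
        preserve_range=True,
    )
    return Hypercube(np.ascontiguousarray(data), cube.wavelengths.copy(), cube.camera, pitch)


def trim_bands(cube: Hypercube, lo_nm: float, hi_nm: float) -> Hypercube:
    """Keep exactly the bands with ``lo_nm <= wavelength <= hi_nm``."""
    if not lo_nm < hi_nm:
        raise ValueError(f"invalid band range [{lo_nm}, {hi_nm}]")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not np.any(keep):
        raise EmptyBandRangeError(f"no bands survive trimming to [{lo_nm}, {hi_nm}] nm")
    return Hypercube(
        np.ascontiguousarray(cube.data[:, :, keep]),
        cube.wavelengths[keep].copy(),
        cube.camera,
        cube.pixel_pitch,
    )


def stitch_spectra(vis_spec: Spectrum, nir_spec: Spectrum) -> Spectrum:
    """Join a VIS and a NIR spectrum into one continuous spectrum.

    The two cameras have independent illumination geometry, which biases
    their reflectance levels against each other. The bias is removed per
    spectrum: the difference between the last VIS value and the first NIR
    value is added to the whole NIR spectrum, making the junction pair
    (951/954 nm on the clinical grids) exactly equal in value.
    """
    if vis_spec.wavelengths[-1] >= nir_spec.wavelengths[0]:
        raise BandGridError(
            "VIS and NIR wavelength ranges overlap: "
            f"{vis_spec.wavelengths[-1]} >= {nir_spec.wavelengths[0]}"
        )
    offset = vis_spec.values[-1] - nir_spec.values[0]
    values = np.concatenate([vis_spec.values, nir_spec.values + offset])
    wavelengths = np.concatenate([vis_spec.wavelengths, nir_spec.wavelengths])
    return Spectrum(values, wavelengths)


def stitch_cubes(vis: Hypercube, nir: Hypercube) -> Hypercube:
    """Per-pixel spectral stitching of two spatially aligned cubes."""
    if (vis.rows, vis.cols) != (nir.rows, nir.cols):
        raise ShapeMismatchError(
            f"spatial shapes differ: VIS {vis.rows}x{vis.cols} vs NIR {nir.rows}x{nir.cols}"
        )
    if vis.wavelengths[-1] >= nir.wavelengths[0]:
        raise BandGridError("VIS and NIR wavelength ranges overlap")
    offset = vis.data[:, :, -1] - nir.data[:, :, 0]
    data = np.concatenate([vis.data, nir.data + offset[:, :, None]], axis=2)
    wavelengths = np.concatenate([vis.wavelengths, nir.wavelengths])
    return Hypercube(data, wavelengths, "STITCHED", vis.pixel_pitch)


def snv_normalize(spec: Spectrum) -> Spectrum:
    """Standard normal variate: (x - mean(x)) / sd(x), sample sd (n-1)."""
    mu = spec.values.mean()
    sigma = spec.values.std(ddof=1)
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateSpectrumError("constant spectrum: SNV undefined")
    return Spectrum((spec.values - mu) / sigma, spec.wavelengths.copy())


def snv_normalize_cube(cube: Hypercube) -> Hypercube:
    """Apply SNV to every pixel spectrum of a cube."""
    mu = cube.data.mean(axis=2, keepdims=True)
    sigma = cube.data.std(axis=2, ddof=1, keepdims=True)
    if np.any(sigma <= 1e-12 * np.maximum(1.0, np.abs(mu))):
        raise DegenerateSpectrumError("cube contains a constant pixel spectrum")
    return Hypercube(
        (cube.data - mu) / sigma, cube.wavelengths.copy(), cube.camera, cube.pixel_pitch
    )


def preprocess_pipeline(
    vis_raw: Hypercube,
    nir_raw: Hypercube,
    refs_vis: CalibrationFrames,
    refs_nir: CalibrationFrames,
    *,
    vis_band_range: tuple[float, float] = VIS_BAND_RANGE,
    nir_band_range: tuple[float, float] = NIR_BAND_RANGE,
    target_rows: int | None = None,
    target_cols: int | None = None,
    target_pitch: float | None = None,
) -> Hypercube:
    """Full chain: calibrate -> resample -> trim -> stitch -> SNV.

    The common spatial grid defaults to the NIR camera's grid (the coarser
    of the clinical pair). Returns a STITCHED cube whose per-pixel spectra
    have zero mean and unit sample standard deviation.
    """
    vis_cal = calibrate_reflectance(vis_raw, refs_vis)
    nir_cal = calibrate_reflectance(nir_raw, refs_nir)
    rows = target_rows if target_rows is not None else nir_cal.rows
    cols = target_cols if target_cols is not None else nir_cal.cols
    pitch = target_pitch if target_pitch is not None else nir_cal.pixel_pitch
    vis_cal, nir_cal = resample_to_common_grid(vis_cal, nir_cal, rows, cols, pitch)
    vis_cal = trim_bands(vis_cal, *vis_band_range)
    nir_cal = trim_bands(nir_cal, *nir_band_range)
    stitched = stitch_cubes(vis_cal, nir_cal)
    return snv_normalize_cube(stitched)
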