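"""Core in-memory containers for hyperspectral data.

A *hypercube* is the 3-D array produced by a pushbroom camera: two spatial
axes (rows, cols) and one spectral axis with a known wavelength for every
band. Reflectance values are dimensionless after flat-field calibration;
before calibration the same container holds raw sensor counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError

#: Valid camera tags. ``STITCHED`` marks the combined VIS+NIR grid.
CAMERA_TAGS = ("VIS", "NIR", "STITCHED")


@dataclass
class Spectrum:
    """A single per-pixel spectrum with its wavelength axis (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape != self.wavelengths.shape or self.values.ndim != 1:
            raise ShapeMismatchError(
                f"spectrum values {self.values.shape} and wavelengths "
                f"{self.wavelengths.shape} must be equal-length 1-D arrays"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CalibrationFrames:
    """White (flat-field) and dark-current reference frames in counts.

    Both frames have the same rows x cols x bands shape as the raw cube
    they calibrate.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ShapeMismatchError(
                f"white {self.white.shape} and dark {self.dark.shape} frames "
                "must have identical shapes"
            )


@dataclass
class Hypercube:
    """Reflectance (or raw-count) cube with wavelength axis and camera tag.

    Parameters
    ----------
    data:
        Array of shape (rows, cols, bands).
    wavelengths:
        Strictly increasing band-center wavelengths in nm, length = bands.
    camera:
        One of ``VIS``, ``NIR``, ``STITCHED``.
    pixel_pitch:
        Spatial sampling in mm/pixel, > 0.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    camera: str
    pixel_pitch: float = 0.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ShapeMismatchError(
                f"hypercube data must be 3-D (rows, cols, bands), got {self.data.shape}"
            )
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ShapeMismatchError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube contains non-finite values")
        if self.camera not in CAMERA_TAGS:
            raise ValueError(f"camera must be one of {CAMERA_TAGS}, got {self.camera!r}")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        """Return the spectrum of a single pixel."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"pixel ({row}, {col}) outside {self.rows}x{self.cols} image")
        return Spectrum(self.data[row, col].copy(), self.wavelengths.copy())
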