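"""Exception types raised across the pipeline."""


class UnmixlabelError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(UnmixlabelError, ValueError):
    """Array shapes of related inputs do not agree."""


class CalibrationError(UnmixlabelError, ValueError):
    """Flat-field calibration is degenerate (white <= dark somewhere)."""


class DegenerateSpectrumError(UnmixlabelError, ValueError):
    """A spectrum is constant, so SNV normalization is undefined."""


class EmptyBandRangeError(UnmixlabelError, ValueError):
    """Band trimming removed every band."""


class BandGridError(UnmixlabelError, ValueError):
    """Wavelength grids are incompatible (overlap, mismatch, wrong order)."""


class BorderPatchError(UnmixlabelError, ValueError):
    """An ink-mark patch crosses the image border."""


class IllPosedUnmixingError(UnmixlabelError, ValueError):
    """The endmember matrix is rank-deficient or otherwise unusable."""
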