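"""Exception hierarchy for the hsisas package."""


class HsisasError(Exception):
    """Base class for all package errors."""


class FormatError(HsisasError):
    """A file on disk does not conform to the expected format."""


class CalibrationError(HsisasError):
    """Reflectance calibration cannot be performed."""


class SegmentationError(HsisasError):
    """Hand/wrist segmentation failed or produced an empty result."""


class DegenerateInputError(HsisasError):
    """Input is degenerate for the requested computation (constant image,
    all-zero differences, zero-variance band, ...)."""


class DimensionError(HsisasError):
    """Array dimensions of the inputs are inconsistent."""
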