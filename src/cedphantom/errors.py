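"""Exception hierarchy shared across the package."""


class CedPhantomError(Exception):
    """Base class for all package errors."""


class ValidationError(CedPhantomError, ValueError):
    """An input violates a documented precondition."""


class RangeError(CedPhantomError, ValueError):
    """A scalar argument falls outside its admissible range."""


class SegmentationError(CedPhantomError):
    """Bolus isolation failed (empty mask, bad seed, ...)."""


class FitError(CedPhantomError):
    """A statistical fit is undefined or degenerate."""


class CalibrationError(CedPhantomError):
    """No usable point on the calibration grid."""
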