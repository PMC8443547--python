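"""Exception hierarchy shared across the pipeline."""


class PalmRamanError(Exception):
    """Base class for all package errors."""


class ValidationError(PalmRamanError):
    """Input violates a documented precondition or invariant."""


class ParseError(PalmRamanError):
    """A file could not be parsed; the message names the offending line."""


class EmptySegmentError(ValidationError):
    """A wavenumber window selected no points."""


class DegenerateDataError(ValidationError):
    """Data carry no usable variation (e.g. zero within-group variance)."""


class UndefinedRatioError(ValidationError):
    """A peak-height ratio has a zero denominator; the message names the feature."""


class CalibrationError(ValidationError):
    """Wavenumber calibration shift exceeds the plausible range."""
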