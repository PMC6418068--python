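"""Exception hierarchy for the pipeline."""


class MurisleepError(Exception):
    """Base class for all package errors."""


class FormatError(MurisleepError):
    """A file does not conform to the expected container layout."""


class ValidationError(MurisleepError):
    """An input violates a documented precondition or invariant."""


class CalibrationError(MurisleepError):
    """Automatic threshold calibration failed; manual thresholds are required."""


class UndefinedMetricError(MurisleepError):
    """A metric is undefined for this recording (e.g. zero sleep time)."""
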