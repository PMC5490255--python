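"""Exception hierarchy.

All package errors derive from :class:`OdortraceError` so callers can catch
pipeline failures without masking programming errors.
"""


class OdortraceError(Exception):
    """Base class for all odortrace errors."""


class TraceValidationError(OdortraceError, ValueError):
    """Raised when a trace or simulation input violates its invariants."""


class FitConvergenceError(OdortraceError):
    """A nonlinear fit failed to converge after bounded restarts.

    Carries the best parameters found so far (may be ``None``) so callers
    can inspect partial results.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class AlignmentError(OdortraceError):
    """The calibration peak required for channel alignment is missing."""


class ResponseOutOfRange(OdortraceError):
    """A response cannot be inverted through the dose-response model.

    ``kind`` distinguishes ``"below_detection"`` (response <= 0) from
    ``"saturated"`` (response >= Rmax).
    """

    def __init__(self, message, kind):
        super().__init__(message)
        self.kind = kind


class NotDetected(OdortraceError):
    """A measured response sits below the detection threshold."""


class PipelineError(OdortraceError):
    """A pipeline stage failed; ``stage`` labels the failing step."""

    def __init__(self, message, stage):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(OdortraceError, ValueError):
    """A run configuration failed schema validation."""
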