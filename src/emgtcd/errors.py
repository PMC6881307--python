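"""Exception hierarchy for the trunk-compensation detection pipeline."""


class EmgTcdError(Exception):
    """Base class for all package errors."""


class ValidationError(EmgTcdError):
    """A domain object violates its invariants."""


class FormatError(EmgTcdError):
    """An on-disk file does not conform to a supported format."""


class ParameterError(EmgTcdError):
    """An operation was called with invalid parameters."""


class SegmentationFailure(EmgTcdError):
    """The optimal-threshold search found no (sec, Th) yielding the expected
    number of active segments anywhere on the grid."""

    def __init__(self, message: str, closest_n: int | None = None):
        super().__init__(message)
        self.closest_n = closest_n


class DegenerateWindowError(EmgTcdError):
    """A window has zero variance, so a model fit on it is undefined."""
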