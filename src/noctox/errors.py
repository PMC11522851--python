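"""Exception hierarchy for the noctox pipeline.

All errors derive from :class:`NoctoxError` so callers can catch pipeline
failures with a single except clause while letting programming errors
(TypeError etc.) propagate.
"""


class NoctoxError(Exception):
    """Base class for all noctox errors."""


class ParseError(NoctoxError):
    """A session or table file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class EmptyInputError(NoctoxError):
    """An input file or series contained no data."""


class MissingDataError(NoctoxError):
    """A required record (e.g. a morning LLS entry) is absent."""


class InsufficientDataError(NoctoxError):
    """Too few samples/pairs for the requested computation."""


class DegenerateRecordingError(NoctoxError):
    """A recording has no usable (artefact-free) samples."""


class DegenerateGroupingError(NoctoxError):
    """A subgroup comparison was requested with an empty group."""


class InputDomainError(NoctoxError):
    """An argument fell outside its documented domain."""


class ConsistencyError(NoctoxError):
    """Component results passed together do not describe the same session."""


class ConfigError(NoctoxError):
    """A configuration value is invalid."""
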