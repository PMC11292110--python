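"""Exception hierarchy for the chromatographic binding pipeline."""


class AffinichromError(Exception):
    """Base class for all package errors."""


class ChromatogramParseError(AffinichromError):
    """Raised when a chromatogram text file cannot be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(AffinichromError):
    """A domain-type invariant was violated."""


class PeakNotFoundError(AffinichromError):
    """No sample rose above the detection threshold: no peak detected."""


class ElutesBeforeVoidError(AffinichromError):
    """Retention time earlier than the void time.

    Invalid for binding analysis; control-column (bare silica) runs may
    legitimately elute at or before the void and are handled separately
    in QC reporting.
    """


class InsufficientDataError(AffinichromError):
    """Too few observations for the requested fit."""


class ParameterExtractionError(AffinichromError):
    """Slope/intercept signs incompatible with saturable binding."""
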