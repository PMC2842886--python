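"""Exception hierarchy for sodphrv."""


class SodphrvError(Exception):
    """Base class for all package errors."""


class ParameterError(SodphrvError, ValueError):
    """An argument or configuration value is out of its valid range."""


class InsufficientDataError(SodphrvError, ValueError):
    """A series is too short for the requested operation."""


class RRParseError(SodphrvError, ValueError):
    """An RR-interval text file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(SodphrvError, ValueError):
    """An input file or collection contained no usable data."""
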