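"""Exception hierarchy shared across the package.

All errors derive from :class:`MarmError` so callers can catch package
failures with a single except clause. The CLI maps :class:`SchemaError`
to exit code 2 and :class:`LeakageError` to exit code 3.
"""


class MarmError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MarmError, ValueError):
    """A configuration value or function argument is out of its domain."""


class InvalidInputError(MarmError, ValueError):
    """Input data violate a structural precondition (shape, emptiness, order)."""


class SchemaError(MarmError, ValueError):
    """A file or table does not match the expected schema; message carries location."""


class ParseError(SchemaError):
    """A text report line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class LeakageError(MarmError, RuntimeError):
    """Evaluation samples were found in a model's training or pseudo-label pool."""


class UndefinedMetricError(MarmError, ValueError):
    """A metric is undefined for the given inputs (e.g. one-class truth)."""
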