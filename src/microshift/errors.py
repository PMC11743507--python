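"""Typed exceptions shared across the package.

Every malformed input raises one of these rather than silently coercing;
callers can catch :class:`MicroshiftError` to trap anything we raise.
"""


class MicroshiftError(Exception):
    """Base class for all package errors."""


class ValidationError(MicroshiftError, ValueError):
    """An input table or vector violates a documented invariant."""


class FormatError(ValidationError):
    """A file cell or field cannot be parsed as its declared type."""


class SchemaError(ValidationError):
    """A file is missing required columns."""


class JoinError(ValidationError):
    """Two tables that must share identifiers do not."""


class ParameterError(MicroshiftError, ValueError):
    """A function argument is outside its documented domain."""


class ConfigError(MicroshiftError, ValueError):
    """A run configuration file is invalid."""


class DegenerateInputError(MicroshiftError, ValueError):
    """Numerically valid input for which the operation is undefined."""
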