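"""Exception hierarchy for the ifsigtt package.

All package errors derive from :class:`IfsigttError` so callers can catch
everything with one except clause while tests can assert on the precise kind.
"""


class IfsigttError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(IfsigttError):
    """Input table is structurally wrong (missing columns, empty file)."""


class IntegrityError(IfsigttError):
    """Input violates uniqueness/consistency (e.g. duplicate subject-time rows)."""


class ParseError(IfsigttError):
    """A cell could not be parsed; the message names the offending row."""


class ValidationError(IfsigttError):
    """Data present but unusable for the requested operation."""


class DomainError(IfsigttError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class FitError(IfsigttError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NumericalError(IfsigttError):
    """Numerical integration or linear algebra failed."""


class PipelineError(IfsigttError):
    """End-to-end analysis cannot proceed (e.g. a group emptied by filtering)."""


class ConfigError(IfsigttError):
    """Configuration file or settings object violates its schema."""
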