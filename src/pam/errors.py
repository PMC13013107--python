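"""Exception hierarchy for the PAM toolkit.

All package errors derive from :class:`PamError` so callers (and the CLI)
can distinguish validation problems (exit code 2) from runtime failures
(exit code 3).
"""


class PamError(Exception):
    """Base class for all PAM errors."""


class ValidationError(PamError):
    """Input failed a precondition (bad argument, out-of-range value)."""


class SchemaError(ValidationError):
    """A tabular input is missing a required column or has a bad header."""


class IntegrityError(ValidationError):
    """Referential or logical integrity violated between records."""


class DataError(ValidationError):
    """A data value is invalid (negative intensity, unhandled zero, ...)."""


class StateError(PamError):
    """An operation was applied in the wrong object state (e.g. double log2)."""


class ConfigError(ValidationError):
    """A configuration object is inconsistent or incomplete."""


class MatchError(PamError):
    """Control matching could not be carried out as requested."""


class QcError(PamError):
    """Quality-control computation is undefined for the given data."""
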