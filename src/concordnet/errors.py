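"""Exception hierarchy for concordnet.

All package errors derive from :class:`ConcordnetError` so callers (and the
CLI) can catch pipeline failures in one place while still distinguishing
configuration mistakes from malformed input data.
"""


class ConcordnetError(Exception):
    """Base class for all concordnet errors."""


class ConfigurationError(ConcordnetError):
    """A setting (column name, probability, path) is invalid or missing."""


class ParseError(ConcordnetError):
    """An input file could not be parsed; the message names row and column."""


class ValidationError(ConcordnetError):
    """Data violates a structural invariant (duplicate IDs, non-binary cell, ...)."""


class EmptyCohortError(ValidationError):
    """Every patient was removed (nobody endorsed any symptom)."""
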