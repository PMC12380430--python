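"""Exception taxonomy.

Every malformed input raises a specific, catchable error; nothing is
silently coerced or NaN-filled.
"""


class OdorAdaptError(Exception):
    """Base class for all package errors."""


class FormatError(OdorAdaptError):
    """A file is missing required columns or structure."""


class ParseError(OdorAdaptError):
    """A value in a file could not be parsed (reported with row context)."""


class ValidationError(OdorAdaptError):
    """Parsed data violate a declared protocol or schema invariant."""


class IntegrityError(OdorAdaptError):
    """A binary container is truncated or internally inconsistent."""


class UsageError(OdorAdaptError):
    """An operation was called with arguments outside its contract."""


class ModelError(OdorAdaptError):
    """A generative model is mis-specified (e.g. negative firing rate)."""


class DegenerateInputError(OdorAdaptError):
    """Input is degenerate for the requested computation (all-zero tensor,
    constant regressor, rank-deficient covariance)."""


class AlignmentError(OdorAdaptError):
    """Two inputs that must share index sets or lengths do not."""


class PairingError(OdorAdaptError):
    """Paired statistics requested on unpairable observations."""


class UndefinedCorrelationError(OdorAdaptError):
    """Pearson correlation requested on a zero-variance vector."""
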