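"""Exception hierarchy shared across the package."""


class TrisskitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TrisskitError):
    """A registry file or coefficient document does not match its schema."""


class RecordValidationError(TrisskitError, ValueError):
    """A patient record (or one of its fields) violates an invariant."""


class CodingError(TrisskitError, ValueError):
    """A physiologic value cannot be banded (out of the coding domain)."""


class ConfigurationError(TrisskitError, ValueError):
    """An unknown policy, mode or switch name was requested."""


class ModelInputError(TrisskitError):
    """A covariate required by a model equation is missing or out of range."""


class ScoringError(TrisskitError):
    """A record cannot be scored by the requested model (with the reason)."""


class ConvergenceError(TrisskitError):
    """An iterative fit failed to converge and the caller asked to raise."""


class RankDeficiencyError(TrisskitError):
    """The design matrix is rank deficient; names the collinear columns."""


class EvaluationError(TrisskitError, ValueError):
    """Discrimination statistics are undefined for the given labels."""
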