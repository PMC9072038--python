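"""Typed error hierarchy.

Every failure mode raised by the package derives from :class:`StfhError`
so callers (and the CLI) can distinguish model errors from programming
errors.
"""


class StfhError(Exception):
    """Base class for all package errors."""


class AdmissibilityError(StfhError, ValueError):
    """A covariance parameter lies outside its admissible interval."""


class ValidationError(StfhError, ValueError):
    """Input data violates a structural invariant."""


class BalanceError(ValidationError):
    """The panel is not balanced: some (area, time) cells are missing."""


class RankError(StfhError, ValueError):
    """The fixed-effect design matrix is rank deficient."""


class ConditioningError(StfhError, ArithmeticError):
    """A covariance matrix is numerically singular at the given parameters."""


class ModelChoiceError(StfhError, ValueError):
    """The requested model is incompatible with the supplied data."""


class ConvergenceError(StfhError, RuntimeError):
    """The optimizer failed to produce a usable fit."""


class BootstrapFailureError(StfhError, RuntimeError):
    """Too many bootstrap replicates failed to converge."""


class DegenerateRegressionError(StfhError, ValueError):
    """A regression diagnostic was called with a constant predictor."""


class SampleSizeError(StfhError, ValueError):
    """Too few observations for the requested diagnostic."""
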