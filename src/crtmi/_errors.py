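"""Exception hierarchy shared across the package."""


class CrtmiError(Exception):
    """Base class for all package errors."""


class ValidationError(CrtmiError, ValueError):
    """A configuration or argument failed validation; names the field."""


class CalibrationError(CrtmiError, RuntimeError):
    """A root-finding calibration (intercept, missingness rate) failed."""


class SeparationError(CrtmiError, RuntimeError):
    """A logistic fit is (quasi-)separated or has one-class outcomes.

    Carries the offending stratum/cluster label so strategy failures can be
    attributed to the unit that caused them.
    """

    def __init__(self, message: str, stratum=None):
        super().__init__(message)
        self.stratum = stratum


class ConvergenceError(CrtmiError, RuntimeError):
    """An iterative fit (EM, quadrature ML, GEE) did not converge."""


class EmptyStratumError(CrtmiError, RuntimeError):
    """A propensity stratum has no observed outcomes to resample from."""

    def __init__(self, message: str, stratum=None):
        super().__init__(message)
        self.stratum = stratum


class NumericalError(CrtmiError, RuntimeError):
    """Covariance repair or matrix factorisation failed beyond recovery."""
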