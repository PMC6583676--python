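"""Exception hierarchy shared across the package."""


class AggsimCeaError(Exception):
    """Base class for all package errors."""


class SchemaError(AggsimCeaError):
    """A required column or field is missing from an input table."""


class ParseError(AggsimCeaError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(AggsimCeaError):
    """A domain invariant is violated (ranges, signs, matrix structure)."""


class CompletenessError(AggsimCeaError):
    """A summary statistic is missing from both the study and the fallback table."""


class CovarianceError(AggsimCeaError):
    """The assembled covariance matrix is not positive semi-definite."""


class InfeasibilityError(AggsimCeaError):
    """Rejection sampling cannot reach the requested sample size."""


class ConfigurationError(AggsimCeaError):
    """A required configuration entry (e.g. a utility coefficient) is unset."""


class EligibilityError(AggsimCeaError):
    """No study is eligible at the requested time point."""


class GridError(AggsimCeaError):
    """The requested horizon is not a grid point of the trajectory."""


class InputError(AggsimCeaError):
    """Generic invalid input (empty collection, negative price, ...)."""
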