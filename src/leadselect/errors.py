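"""Exception types shared across the pipeline."""


class LeadSelectError(Exception):
    """Base class for all package errors."""


class SchemaError(LeadSelectError):
    """A survey table violates the documented column schema or a record invariant."""


class MissingCovariateError(LeadSelectError):
    """A record lacks a covariate required by the requested model specification."""


class UndefinedFeatureError(LeadSelectError):
    """A feature is undefined for the given input (e.g. direction at the dump site)."""


class CollinearityError(LeadSelectError):
    """The design matrix is rank deficient.

    Carries the names of the offending columns; collinear columns are never
    dropped silently.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; suspect columns: {self.columns}")


class SeparationError(LeadSelectError):
    """Probit estimation diverged, indicating (quasi-)complete separation."""


class ConvergenceError(LeadSelectError):
    """An iterative fit failed to converge within the iteration budget."""


class UndefinedStatisticError(LeadSelectError):
    """A statistic is undefined for the given data (e.g. t test with zero variance)."""
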