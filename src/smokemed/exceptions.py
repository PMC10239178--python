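"""Exception hierarchy for the mediation pipeline."""


class SmokemedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmokemedError):
    """A simulation-truth or grid configuration field is invalid."""


class DegenerateInputError(SmokemedError):
    """Input has no usable variation (all missing, zero variance, ...)."""


class DomainError(SmokemedError):
    """A value is outside the mathematical domain of the requested transform."""


class InsufficientDataError(SmokemedError):
    """Too few rows survive subsetting / listwise deletion to fit a model."""


class CollinearityError(SmokemedError):
    """Design matrix is rank deficient (or a VIF is infinite)."""

    def __init__(self, message: str, columns: tuple = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class SpecificationError(SmokemedError):
    """A model/mediation specification names terms that do not exist."""


class InstabilityError(SmokemedError):
    """Too many bootstrap replicates failed to refit."""
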