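"""Exception hierarchy shared across the package."""


class PoemodError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PoemodError):
    """A simulation or pipeline configuration is invalid."""


class DataError(PoemodError):
    """Input data violate a precondition (dimensions, ranges, missingness)."""


class UninformativeSNPError(DataError):
    """A SNP carries no usable genotype information (all missing or monomorphic)."""


class RankDeficiencyError(DataError):
    """A regression design matrix is rank deficient.

    ``columns`` names the offending (linearly dependent) design columns.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class InsufficientDataError(DataError):
    """Too few complete cases to fit the requested model."""
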