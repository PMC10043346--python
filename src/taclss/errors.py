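"""Exception hierarchy shared across the pipeline stages."""


class TaclssError(Exception):
    """Base class for all package errors."""


class ConfigError(TaclssError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(TaclssError):
    """Malformed input data (profiles, cohort tables)."""


class InvalidDoseError(TaclssError):
    """Non-positive weight-normalized dose where a positive one is required."""


class InvalidExposureError(TaclssError):
    """Non-positive AUC where a positive reference exposure is required."""


class EmptyCountsError(TaclssError):
    """Genotype count table with zero total."""


class DegenerateCountsError(TaclssError):
    """Hardy-Weinberg expected class of zero with non-zero observed count."""


class SingularDesignError(TaclssError):
    """Rank-deficient regression design matrix."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class MissingSampleError(TaclssError):
    """Concentration profile lacks a time-point an equation requires."""
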