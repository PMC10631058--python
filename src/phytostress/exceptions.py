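"""Exception hierarchy shared across the package."""


class PhytostressError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(PhytostressError):
    """Experimental design with non-positive counts or empty level lists."""


class ConfigurationError(PhytostressError):
    """Invalid or incomplete configuration (response model, scenario, grid)."""


class SchemaError(PhytostressError):
    """Tabular input missing required columns or otherwise malformed."""


class DegenerateInputError(PhytostressError):
    """Input too small or empty to compute the requested quantity."""


class ContractError(PhytostressError):
    """A value violates an internal invariant (e.g. unnormalized GLCM)."""


class InvalidFoldsError(PhytostressError):
    """Cross-validation fold request that cannot be satisfied."""


class UndefinedMetricError(PhytostressError):
    """Metric denominator is zero (e.g. constant observed values for R^2)."""


class UndefinedSharesError(PhytostressError):
    """All raw importance values are zero after flooring; shares undefined."""
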