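"""Exception hierarchy for cohort validation and model fitting."""


class PalcostError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PalcostError):
    """A required column or field is missing or mistyped."""


class ValidationError(PalcostError):
    """A record violates a data invariant (e.g. pc_day > los_days)."""


class ParameterError(PalcostError):
    """An invalid generator or model parameter."""


class DimensionError(PalcostError):
    """A flag vector does not match the weight table's condition count."""


class SeparationError(PalcostError):
    """Perfect or quasi-perfect separation in the propensity model."""


class ConvergenceError(PalcostError):
    """A model fit, or too many bootstrap replicates, failed to converge."""
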