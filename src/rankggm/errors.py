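"""Exception hierarchy shared across the package."""


class RankGGMError(Exception):
    """Base class for all package errors."""


class SchemaError(RankGGMError):
    """A table's columns do not match the declared variable schema."""


class ValidationError(RankGGMError):
    """Cell values violate the schema (range, type, or required field)."""


class InsufficientDataError(RankGGMError):
    """Too few subjects or complete pairs to run an operation."""


class ConfigurationError(RankGGMError):
    """A generator or analysis configuration is internally inconsistent."""


class DegenerateVariableError(RankGGMError):
    """A variable is constant (or otherwise uninformative) in a stratum."""


class SamplerError(RankGGMError):
    """The Gibbs sampler reached an invalid numerical state."""


class MatrixError(RankGGMError):
    """A matrix argument is not symmetric / positive definite as required."""


class ComparisonError(RankGGMError):
    """Two posterior samples or network estimates are not comparable."""


class DegenerateSimulationError(RankGGMError):
    """A simulation produced an empty or unusable cohort."""
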