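"""Exception hierarchy shared across the package."""


class PbtgermError(Exception):
    """Base class for all package errors."""


class FormatError(PbtgermError):
    """Input file is malformed (missing columns, bad types)."""


class ValidationError(PbtgermError):
    """Data violate an invariant (e.g. decreasing cumulative counts)."""


class UndefinedPercentileError(ValidationError):
    """A requested germination percentile is not attained by the data/model."""


class FitError(PbtgermError):
    """A model fit could not be performed or produced invalid parameters."""


class DegenerateFitError(FitError):
    """Probit regression has no usable variation (constant predictor etc.)."""


class SearchFailure(FitError):
    """Every candidate in a repeated-probit search was degenerate."""


class ConfigError(PbtgermError):
    """Pipeline/CLI configuration is invalid."""
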