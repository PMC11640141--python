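"""Exception hierarchy for the ch4meta pipeline.

Every stage raises a subclass of :class:`Ch4MetaError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class Ch4MetaError(Exception):
    """Base class for all ch4meta errors."""


class ConfigurationError(Ch4MetaError):
    """Invalid generator or pipeline configuration."""


class GenerationError(Ch4MetaError):
    """Synthetic-data generation failed (e.g. missing required predictor)."""


class HarmonizationError(Ch4MetaError):
    """A harmonization formula is missing a required input field."""


class ConsistencyError(HarmonizationError):
    """Observed fields violate an energy-balance identity beyond tolerance."""


class ImputationError(HarmonizationError):
    """No digestibility measurement available to anchor the imputation cascade."""


class ConversionError(HarmonizationError):
    """A methane unit conversion lacks a required context field."""


class ValidationError(Ch4MetaError):
    """A record or table violates the CSV schema."""


class PredictionError(Ch4MetaError):
    """An equation was evaluated without all of its required predictors."""


class NumericError(Ch4MetaError):
    """An equation produced a non-finite prediction."""


class RankError(Ch4MetaError):
    """Too few records for the requested regression."""


class ConvergenceError(Ch4MetaError):
    """A mixed-model fit failed to converge under every fallback structure."""


class SelectionError(Ch4MetaError):
    """Model selection was asked to choose among zero converged fits."""


class EvaluationError(Ch4MetaError):
    """Degenerate input to an evaluation statistic (e.g. zero variance)."""
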