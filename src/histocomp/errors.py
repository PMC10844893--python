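"""Exception hierarchy used across the pipeline."""


class HistocompError(Exception):
    """Base class for all histocomp errors."""


class ConfigError(HistocompError):
    """Invalid simulation or analysis configuration."""


class EmptyResultError(HistocompError):
    """An operation removed or matched nothing where a non-empty result is required."""


class MissingGeneError(HistocompError):
    """A required gene/feature is absent from the matrix or model."""


class NormalizationError(HistocompError):
    """Normalization undefined for the given input (zero library, zero IgG, ...)."""


class ConvergenceError(HistocompError):
    """Iterative fit failed to converge within the iteration budget."""


class SeparationError(ConvergenceError):
    """Monotone partial likelihood: a covariate perfectly orders the events."""
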