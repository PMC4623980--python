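"""Exception hierarchy. All errors derive from ValueError so callers can
catch them generically without importing this module."""


class TunabioError(ValueError):
    """Base class for package errors."""


class ConfigurationError(TunabioError):
    """Invalid generator, fleet or pipeline configuration."""


class FitError(TunabioError):
    """A regression could not be fitted (degenerate input, non-convergence)."""


class SchemaError(TunabioError):
    """An input table is missing required columns or has invalid values."""


class PipelineError(TunabioError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
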