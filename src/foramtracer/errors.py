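"""Exception hierarchy shared across the pipeline stages."""


class ForamTracerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ForamTracerError, ValueError):
    """A value violates a physical or mathematical precondition."""


class SchemaError(ForamTracerError, ValueError):
    """An input table does not conform to the expected schema."""


class DegenerateLabelError(InvalidInputError):
    """Food-source enrichment does not exceed the background; mixing is undefined."""


class InconsistentMassError(InvalidInputError):
    """A mass correction would consume the entire measured mass."""


class SingularFitError(ForamTracerError, ValueError):
    """Regression design is degenerate (collinear or constant predictor)."""


class ConfigurationError(ForamTracerError, ValueError):
    """Inconsistent pipeline or scenario configuration."""
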