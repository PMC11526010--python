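"""Exception hierarchy shared across the package."""


class VepmetaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VepmetaError):
    """An invalid configuration value or inconsistent option combination."""


class GenerationError(VepmetaError):
    """The synthetic generator cannot satisfy the requested constraints."""


class SchemaError(VepmetaError):
    """A table or matrix does not conform to the expected schema."""


class ParseError(VepmetaError):
    """A file could not be parsed; the message names the offending line."""


class UndefinedMetricError(VepmetaError):
    """A metric is undefined for the given input (e.g. an empty class)."""


class ValidationError(VepmetaError):
    """An input object violates a structural invariant (e.g. asymmetry)."""


class TuningError(VepmetaError):
    """Hyperparameter tuning failed to produce any usable configuration."""
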