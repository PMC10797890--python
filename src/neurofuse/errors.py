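class NeurofuseError(ValueError):
    """Base class for all validation and configuration errors."""


class ConfigError(NeurofuseError):
    """Raised when a configuration object fails validation; names the field."""
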