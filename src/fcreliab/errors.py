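"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented invariant; message names the invariant."""


class ConfigError(ValidationError):
    """A run configuration is invalid (missing path, bad option)."""
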