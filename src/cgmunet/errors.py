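"""Exception types shared across the package."""


class DimensionError(ValueError):
    """A tensor shape violates a divisibility or consistency requirement."""


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


class ValidationError(ValueError):
    """Input data violates a data contract (e.g. a mask is not binary)."""
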