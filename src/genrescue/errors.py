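"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a scenario, genome, or schedule parameter is invalid."""
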