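"""Exception types shared across the toolkit."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented invariant."""


class StageError(RuntimeError):
    """A pipeline stage failed; upstream artifacts are preserved."""
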