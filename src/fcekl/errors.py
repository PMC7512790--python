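"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid model or ensemble configuration (e.g. more clusters than data)."""


class DegenerateInputError(ValueError):
    """Input admits no meaningful fit (e.g. constant image, zero intensity range)."""


class EmptyClusterError(RuntimeError):
    """A consensus cluster lost all membership mass; re-seed the initialization."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
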