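"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(ValueError):
    """An input collection or file cannot be used (empty, malformed...)."""


class InsufficientDataError(ValueError):
    """Too little data to compute a statistic reliably."""
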