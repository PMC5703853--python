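"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(ValueError):
    """The data admit no well-defined answer (e.g. zero-variance paired differences)."""
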