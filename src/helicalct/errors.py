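"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class CoverageError(RuntimeError):
    """The acquired helical data do not cover the requested plane or angle."""
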