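"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data or configuration violates a documented contract.

    The CLI maps this to exit code 2; any other exception is an internal
    error (exit code 1).
    """
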