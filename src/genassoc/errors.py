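"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid configuration, parameter, or input value."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending row/column."""
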