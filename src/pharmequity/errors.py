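"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input value falls outside its documented domain."""


class SchemaError(ValidationError):
    """Raised when a tabular input is missing required columns."""
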