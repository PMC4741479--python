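"""Exception hierarchy shared across the pipeline."""


class RadiomirError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RadiomirError):
    """A file does not conform to the expected tabular dialect
    (missing column, non-numeric cell, wrong header)."""


class ValidationError(RadiomirError):
    """Well-formed input that violates a domain invariant
    (negative intensity, unknown group label, duplicate id)."""
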