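"""Exception hierarchy shared across the package."""


class BmecvError(ValueError):
    """Base class for all package errors."""


class FormatError(BmecvError):
    """A file could not be parsed (ragged rows, bad characters, ...)."""


class ValidationError(BmecvError):
    """Inputs are syntactically fine but semantically invalid."""


class NumericError(BmecvError):
    """A computation produced non-finite values despite safeguards."""
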