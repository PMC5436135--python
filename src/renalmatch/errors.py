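"""Exception hierarchy shared across the pipeline."""


class RenalmatchError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RenalmatchError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(RenalmatchError, ValueError):
    """A file violates its declared dialect; message names the offending line."""


class DegenerateInputError(RenalmatchError, ValueError):
    """Input is structurally valid but carries no usable information
    (empty profile, all-zero copy number, ...)."""
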