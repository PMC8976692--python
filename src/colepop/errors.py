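"""Exception hierarchy shared across the package."""


class ColepopError(Exception):
    """Base class for all package errors."""


class ParseError(ColepopError):
    """A file could not be parsed (malformed VCF, Newick, TSV...)."""


class ValidationError(ColepopError):
    """Parsed content violates a domain invariant."""


class EmptyInputError(ColepopError):
    """An input contained no usable records."""
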