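"""Exception hierarchy shared across the package."""


class CphmdkitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CphmdkitError):
    """A file could not be parsed (malformed line, unknown token, ...)."""


class DataError(CphmdkitError):
    """Input data violate a precondition of an analysis step."""
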