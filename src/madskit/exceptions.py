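"""Exception hierarchy shared across madskit modules."""


class MadskitError(Exception):
    """Base class for all madskit errors."""


class ValidationError(MadskitError, ValueError):
    """Invalid input data or parameters."""


class ParseError(ValidationError):
    """Malformed textual specification (mutation strings, patterns, files)."""


class CoordinateError(ValidationError):
    """A sequence coordinate is out of range or does not match expectations."""
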