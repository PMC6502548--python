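"""Exception hierarchy.

``ValidationError`` covers bad user input (malformed files, unknown labels,
invalid configuration) and maps to CLI exit code 2; any other exception is
an internal error (exit code 1).
"""


class CitsiftError(Exception):
    """Base class for package errors."""


class ValidationError(CitsiftError, ValueError):
    """Invalid input data or configuration."""


class ParseError(ValidationError):
    """A file could not be parsed; message carries file/line context."""
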