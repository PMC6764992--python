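"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad files, violated
preconditions); the CLI maps it to exit code 2.  Everything else is an
internal error (exit code 1).
"""


class ValidationError(ValueError):
    """Input failed a documented precondition or format check."""


class ParseError(ValidationError):
    """A cell or row of an input file could not be parsed."""
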