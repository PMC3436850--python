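"""Exception hierarchy.

``SpliceQuantError`` is the base for everything the package raises on
purpose; callers (and the CLI) can distinguish input problems
(``ParseError``/``ValidationError``, exit code 1) from runtime faults
(anything else, exit code 2).
"""


class SpliceQuantError(Exception):
    """Base class for all errors raised by splicequant."""


class ParseError(SpliceQuantError):
    """A file could not be parsed; carries enough context to find the line."""


class ValidationError(SpliceQuantError):
    """Parsed input violates a documented invariant."""
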