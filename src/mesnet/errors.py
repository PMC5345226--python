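"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: validation failures exit 1,
I/O and parse failures exit 2.
"""


class MesnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MesnetError):
    """Input violates a documented precondition or invariant."""


class ParseError(MesnetError):
    """A file could not be parsed; message names the offending location."""
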