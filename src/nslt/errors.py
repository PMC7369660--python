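"""Exception hierarchy.

The CLI maps :class:`ValidationError` (and subclasses) to exit code 2 and
I/O failures to exit code 3; library code raises, never exits.
"""


class NSLTError(Exception):
    """Base class for all package errors."""


class ValidationError(NSLTError, ValueError):
    """A precondition on user input or configuration was violated."""


class EmptyForegroundError(ValidationError):
    """No pixel exceeds the background threshold; nothing to crop."""


class DegenerateImageError(ValidationError):
    """A map that must be non-constant (local mean, homogeneity) is constant."""


class SchemaError(ValidationError):
    """Feature-vector or table column sets do not match."""


class ProtocolError(ValidationError):
    """Evaluation protocol cannot run (e.g. a single-class table)."""
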