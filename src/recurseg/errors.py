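"""Exception hierarchy.

``InputError`` covers malformed or degenerate user data (CLI exit code 2);
``ContractViolationError`` covers arguments that break a documented
precondition (CLI exit code 3).
"""


class RecursegError(Exception):
    """Base class for all package errors."""


class InputError(RecursegError):
    """Malformed, empty or degenerate input data."""


class DimensionError(InputError):
    """Incompatible array shapes or vector lengths."""


class ParameterError(RecursegError):
    """A parameter outside its admissible range."""


class ContractViolationError(RecursegError):
    """An argument violating a documented precondition (e.g. non-unit states)."""
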