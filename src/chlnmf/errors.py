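"""Exception hierarchy.

All errors raised by this package derive from :class:`ChlnmfError` so callers
can catch everything from one base.  The two ``ValueError`` subclasses
distinguish bad *data* (malformed matrices, shape mismatches, negative
entries) from bad *parameters* (an out-of-range knob the caller chose).
"""


class ChlnmfError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ChlnmfError, ValueError):
    """The input data violate a precondition (shape, sign, finiteness, ids)."""


class InvalidParameterError(ChlnmfError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class NumericalError(ChlnmfError, ArithmeticError):
    """Non-finite values or an inconsistency appeared during computation."""


class PipelineError(ChlnmfError, RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""
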