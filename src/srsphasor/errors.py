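"""Exception hierarchy shared across the package.

The CLI maps :class:`ValidationError` (bad inputs, bad config) to exit code 2
and every other :class:`SrsPhasorError` to exit code 1.
"""


class SrsPhasorError(Exception):
    """Base class for all errors raised by srsphasor."""


class ValidationError(SrsPhasorError, ValueError):
    """An input violates a structural invariant (shape, ordering, duplication)."""


class FormatError(ValidationError):
    """An on-disk artifact is malformed or inconsistent with its sidecar."""


class DomainError(SrsPhasorError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class OutOfRangeError(DomainError):
    """A requested wavenumber falls outside the axis of a stack."""


class DegenerateInputError(DomainError):
    """An input is too degenerate for the operation (e.g. a constant spectrum)."""


class PlacementError(SrsPhasorError, RuntimeError):
    """Scene geometry could not be realised within the retry budget."""
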