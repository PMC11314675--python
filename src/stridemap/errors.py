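"""Exception hierarchy shared by all stridemap modules."""


class StrideMapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StrideMapError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(StrideMapError, ValueError):
    """A query time or position falls outside the supported span."""

    def __init__(self, message: str, offending=None):
        super().__init__(message)
        self.offending = list(offending) if offending is not None else []


class MissingTimeError(StrideMapError, ValueError):
    """A GPX track carries no timestamps, so it cannot be interpolated."""


class ConsistencyError(StrideMapError, RuntimeError):
    """A map store mutation would break referential symmetry."""


class PathTypeMismatchError(StrideMapError, ValueError):
    """Two paths of different types were asked to merge; treated as non-matching."""
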