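"""Exception hierarchy shared across the package."""


class ZDosageError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(ZDosageError, ValueError):
    """A simulation design or analysis configuration violates its invariants."""


class InvalidInputError(ZDosageError, ValueError):
    """An operation received data that violates its preconditions."""


class InsufficientDataError(ZDosageError, ValueError):
    """Not enough observations to perform the requested computation."""


class DegenerateSampleError(ZDosageError, ValueError):
    """A sample is unusable (e.g. all-zero counts); the message names it."""


class IncomparablePairError(ZDosageError, ValueError):
    """A sequence pair shares no comparable (non-gap) alignment columns."""


class NotFoundError(ZDosageError, KeyError):
    """A requested record id is absent from the input."""


class OutOfRangeError(ZDosageError, ValueError):
    """A coordinate window falls outside the sequence it addresses."""


class ParseError(ZDosageError, ValueError):
    """Malformed input file or string; carries the offending position."""

    def __init__(self, message: str, *, line: int | None = None,
                 position: int | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if position is not None:
            loc.append(f"position {position}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.line = line
        self.position = position
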