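"""Exception hierarchy for binimpute."""


class BinimputeError(Exception):
    """Base class for all binimpute errors."""


class FormatError(BinimputeError, ValueError):
    """A file or table does not have the expected layout."""


class EmptyInputError(BinimputeError, ValueError):
    """No usable data after parsing/filtering."""


class InsufficientDaysError(BinimputeError, ValueError):
    """Fewer complete days available than requested."""

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(
            f"requested {requested} complete days but only {available} available"
        )


class GapError(BinimputeError, ValueError):
    """A gap specification cannot be applied to the matrix."""


class BinError(BinimputeError, ValueError):
    """A bin window cannot be constructed or extracted."""


class NumericalError(BinimputeError, ArithmeticError):
    """A linear-algebra step failed; usually fixed by setting ridge > 0."""


class IncompleteGridError(BinimputeError, ValueError):
    """An evaluation statistic is missing required (day, bin, method) cells."""
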