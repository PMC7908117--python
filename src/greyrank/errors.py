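"""Exception hierarchy for greyrank.

Every error raised by the library derives from :class:`GreyRankError`, so
callers (and the CLI) can catch one type. Subclasses map onto the distinct
failure modes of the sequence operators, the degree models, and the I/O
layer.
"""


class GreyRankError(Exception):
    """Base class for all greyrank errors."""


class ZeroMeanError(GreyRankError):
    """A series with zero arithmetic mean cannot be mean-normalized."""


class ZeroInitialError(GreyRankError):
    """A series whose first value is zero has no initial-value image."""


class LengthError(GreyRankError):
    """Series lengths are mismatched or too short for the operation."""


class InvalidEpsilonError(GreyRankError):
    """Resolution coefficient outside the open-closed interval (0, 1]."""


class InvalidThetaError(GreyRankError):
    """Synthesis weight theta outside [0, 1]."""


class EmptyInputError(GreyRankError):
    """An operation received no comparators / no degrees to rank."""


class SpecError(GreyRankError):
    """Invalid synthetic-panel specification."""


class ParseError(GreyRankError):
    """A panel file could not be parsed; message names the offending cell."""


class MissingReferenceError(GreyRankError):
    """The requested reference column is absent from the input file."""
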