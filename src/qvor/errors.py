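"""Exception hierarchy for the qvor pipeline.

Every stage raises a subclass of :class:`QvorError` so callers can catch
pipeline failures without masking programming errors.
"""


class QvorError(Exception):
    """Base class for all qvor-specific errors."""


class FormatError(QvorError):
    """A required column or field is missing from an input file."""


class ParseError(QvorError):
    """A cell could not be parsed; the message names the offending row."""


class TimingError(QvorError):
    """Timestamps are non-monotone or non-uniform beyond tolerance."""


class ValidationError(QvorError):
    """A domain object violates its invariants."""


class TooShortError(QvorError):
    """A recording is shorter than the operation requires."""


class CoverageError(QvorError):
    """The requested analysis window is not covered by the trace."""


class DesaccadeError(QvorError):
    """Saccade removal left too few slow-phase samples to fit."""


class EstimationError(QvorError):
    """A gain or frequency estimate could not be formed."""


class DegenerateInputError(EstimationError):
    """Head velocity carries no usable signal (e.g. all near zero)."""


class InsufficientDataError(QvorError):
    """A statistical test was requested with too few observations."""


class PairingError(QvorError):
    """A subject is missing one of its paired VVOR/VORS recordings."""
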