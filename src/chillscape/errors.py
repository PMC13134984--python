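"""Exception hierarchy shared across the package.

Everything derives from :class:`ChillscapeError` so callers can catch one
base class; most classes also derive from ``ValueError`` because they signal
bad arguments or unusable samples.
"""


class ChillscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ChillscapeError, ValueError):
    """An argument is outside its documented domain."""


class InvalidDateError(InvalidArgumentError):
    """A month/day pair that does not exist in the 365-day calendar."""


class InvalidRangeError(InvalidArgumentError):
    """A year span too short for the requested moving windows."""


class UnsupportedLatitudeError(InvalidArgumentError):
    """Latitude outside the non-polar band the solar geometry supports."""


class DegenerateDaylengthError(ChillscapeError, ValueError):
    """Daylength too short (or night too short) for the diurnal curve."""


class MissingDataError(ChillscapeError, ValueError):
    """A seasonal window is not fully covered by the supplied series."""


class EmptySampleError(ChillscapeError, ValueError):
    """An empirical distribution was requested from zero observations."""


class InsufficientSampleError(ChillscapeError, ValueError):
    """Fewer observations than the statistic needs."""


class CalibrationMismatchError(ChillscapeError, ValueError):
    """Observed and modelled calibration series differ in length."""


class AlignmentError(ChillscapeError, ValueError):
    """Ensemble members do not share the same cells and dates."""


class InvalidGridError(ChillscapeError, ValueError):
    """A grid lacks the lattice structure an operation requires."""
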