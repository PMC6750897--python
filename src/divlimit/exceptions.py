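"""Exception hierarchy for divlimit.

All domain errors derive from :class:`DivlimitError` so callers can catch
one base class; most also derive from the matching builtin (ValueError)
so sloppy call sites still fail loudly.
"""


class DivlimitError(Exception):
    """Base class for all divlimit errors."""


class InvalidParameterError(DivlimitError, ValueError):
    """A model parameter violates its domain (e.g. R0 <= 0, t < 0)."""


class DegenerateAlphabetError(InvalidParameterError):
    """Effective alphabet size a <= 1: the site cannot diverge."""


class SaturationError(DivlimitError, ValueError):
    """Identity at or below the 1/a floor: evolutionary distance undefined."""


class TooFewTimepointsError(DivlimitError, ValueError):
    """Observations span fewer distinct divergence times than required."""


class InsufficientDataError(DivlimitError, ValueError):
    """Not enough observations for the requested statistic."""


class DegenerateFitError(DivlimitError, ValueError):
    """A fit whose standard errors are zero or undefined."""


class ConfigurationError(DivlimitError, ValueError):
    """Inputs missing fields the requested analysis needs."""


class UndefinedIdentityError(DivlimitError, ValueError):
    """Percent identity requested for an alignment with no aligned columns."""


class CalibrationError(DivlimitError, ValueError):
    """Distance-to-time calibration points are degenerate."""


class InsufficientOverlapError(DivlimitError, ValueError):
    """Gene and species trees share too few taxa to be compared."""
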