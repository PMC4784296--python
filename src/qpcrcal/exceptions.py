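"""Exception hierarchy for plate parsing and curve analysis failures.

Callers that process whole plates catch the per-well analysis errors
(`NoAmplificationError`, `ShortWindowError`, ...) and flag the well rather
than aborting the run; the I/O and calibration errors are fatal.
"""


class QpcrCalError(Exception):
    """Base class for all package errors."""


# --- plate I/O -------------------------------------------------------------

class RaggedPlateError(QpcrCalError):
    """A well is missing one or more cycle readings."""


class DuplicateReadingError(QpcrCalError):
    """The same (well, cycle) pair appears more than once."""


class PlateMapError(QpcrCalError):
    """Malformed plate-map row (unknown role, missing calibrator amount...)."""


class OrphanWellError(QpcrCalError):
    """A well has fluorescence data but no plate-map entry."""


# --- curve analysis --------------------------------------------------------

class ShortCurveError(QpcrCalError):
    """Too few cycles to establish a baseline."""


class NoAmplificationError(QpcrCalError):
    """No rise above baseline noise; typical for NTC wells."""


class DegenerateCurveError(QpcrCalError):
    """Landmarks cannot be located (e.g. take-off threshold never crossed)."""


class ShortWindowError(QpcrCalError):
    """Exponential window has fewer than three usable cycles."""


class CannotEstimateError(QpcrCalError):
    """Efficiency regression impossible (fewer than three positive points)."""


# --- calibration -----------------------------------------------------------

class MissingBackgroundError(QpcrCalError):
    """No 0 ng calibrator well on the plate."""


class InsufficientLevelsError(QpcrCalError):
    """Fewer than five distinct non-zero calibrator levels."""


class NonPositiveSlopeError(QpcrCalError):
    """Calibration slope is not positive; the curve is unusable."""


# --- quantification --------------------------------------------------------

class CannotQuantifyError(QpcrCalError):
    """Fewer than three window cycles survive back-calculation."""


class InvalidEfficiencyError(QpcrCalError):
    """Efficiency <= 1 cannot be used for back-calculation."""
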