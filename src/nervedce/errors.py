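"""Exception hierarchy for the nervedce pipeline.

Every stage raises a distinct subclass of :class:`NerveDceError` so that
callers (and the CLI) can map error families to exit codes.
"""


class NerveDceError(Exception):
    """Base class for all nervedce errors."""


# --- VFA T1 mapping -------------------------------------------------------

class DegenerateAngle(NerveDceError):
    """Flip angle at 0 or 90 degrees: tan/sin linearization is undefined."""


class NonphysicalSlope(NerveDceError):
    """VFA regression slope outside (0, 1): T1 would be negative/infinite."""


class InsufficientAngles(NerveDceError):
    """Fewer than two distinct flip angles: regression is underdetermined."""


# --- concentration conversion ---------------------------------------------

class MissingBaseline(NerveDceError):
    """No pre-bolus baseline defined for the dynamic series."""


class SignalOutOfRange(NerveDceError):
    """Signal enhancement outside the invertible spoiled-GRE domain."""


class NonphysicalConcentration(NerveDceError):
    """Concentration implying a non-positive post-contrast T1."""


# --- AIF extraction --------------------------------------------------------

class EmptyRoi(NerveDceError):
    """Region of interest contains no voxels."""


class NoBolusDetected(NerveDceError):
    """No time point exceeds the running-baseline threshold."""


# --- extended Tofts model --------------------------------------------------

class DegenerateVe(NerveDceError):
    """ve = 0 with Ktrans > 0: washout rate Ktrans/ve is undefined."""


class NoValidData(NerveDceError):
    """No valid time points left to fit."""


# --- cohort statistics -----------------------------------------------------

class InvalidScore(NerveDceError):
    """Clinical score outside its admissible range."""


class MissingMeasurement(NerveDceError):
    """A required clinical measurement is missing."""


class InsufficientData(NerveDceError):
    """Too few observations for the requested test."""


class UseTwoGroupPath(NerveDceError):
    """Fewer than three groups passed to the multi-group comparison."""


class UndefinedCorrelation(NerveDceError):
    """Zero variance in one of the variables: correlation undefined."""


class CollinearControls(NerveDceError):
    """Control covariates are collinear; partial correlation undefined."""


class SchemaError(NerveDceError):
    """Cohort table is missing a required column."""


# --- synthetic cohort ------------------------------------------------------

class InvalidCorrelationTarget(NerveDceError):
    """Target correlation matrix cannot be repaired to positive semi-definite."""


class InvalidBolusTime(NerveDceError):
    """Bolus arrival time is not a finite, non-negative instant."""


class InvalidNoise(NerveDceError):
    """Negative noise standard deviation."""


# --- I/O and pipeline ------------------------------------------------------

class ShapeError(NerveDceError):
    """Volume/mask dimension mismatch or malformed input file."""
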