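"""Exception hierarchy for mammospat.

All package-specific failures derive from :class:`MammospatError` so callers
can catch one base class at pipeline level.
"""


class MammospatError(Exception):
    """Base class for all mammospat errors."""


class InvalidSpecError(MammospatError):
    """A phantom/cohort/fixture specification violates its invariants."""


class CalibrationFailureError(MammospatError):
    """The cohort intercept calibration cannot reach the requested case fraction."""


class InvalidImageError(MammospatError):
    """An image contains non-finite pixels or violates intensity bounds."""


class DegenerateHistogramError(MammospatError):
    """Too few occupied histogram bins for the requested number of classes."""


class NoBreastFoundError(MammospatError):
    """Foreground segmentation produced an empty candidate mask."""


class DegenerateInputError(MammospatError):
    """Clustering input has fewer distinct values than requested clusters."""


class InvalidTargetError(MammospatError):
    """Label-map rescaling was asked to upsample (target spacing < source)."""


class InvalidLabelMapError(MammospatError):
    """A label map violates its contract (e.g. overlapping regions)."""


class InvalidPairError(MammospatError):
    """A forces histogram was requested for an invalid region pair (i == j)."""


class InsufficientDataError(MammospatError):
    """Too few curves/observations to fit the requested model."""


class DegenerateDataError(MammospatError):
    """Data with zero variance (or similar) where variation is required."""


class IncompatibleGridError(MammospatError):
    """New curves are sampled on a different grid than the fitted model."""


class SeparationError(MammospatError):
    """Complete or quasi-complete separation in a logistic regression."""


class DesignError(MammospatError):
    """Rank-deficient or otherwise invalid regression design matrix."""


class InvalidComparisonError(MammospatError):
    """Likelihood-ratio test requested for non-nested or mismatched models."""


class UndefinedAUCError(MammospatError):
    """AUC requested with only one class present in the labels."""


class JoinError(MammospatError):
    """Image identifiers and covariate rows could not be matched 1:1."""
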