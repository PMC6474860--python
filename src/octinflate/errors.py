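"""Exception hierarchy for the inflation-analysis pipeline."""


class OctInflateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OctInflateError, ValueError):
    """A forward-model or configuration parameter is outside its valid range."""


class FieldOfViewError(OctInflateError):
    """Requested geometry would place a surface outside the rendered image."""


class SegmentationError(OctInflateError):
    """Boundary detection failed on too many image columns."""


class SurfaceConsistencyError(OctInflateError):
    """Posterior trace ended up above the anterior trace after filtering."""


class WindowCoverageError(OctInflateError):
    """Surface traces do not cover the required lateral analysis window."""


class DegenerateFitError(OctInflateError):
    """Geometric fit is degenerate (e.g. collinear points for a circle)."""


class MissingReferenceError(OctInflateError):
    """The 2 mmHg loading reference state required for strain is absent."""


class DisjointStrainError(OctInflateError):
    """Loading and unloading curves share no strain range to integrate over."""


class FitConvergenceError(OctInflateError):
    """Nonlinear least-squares fit failed to converge."""


class CalibrationError(OctInflateError):
    """Bisection calibration could not bracket or reach its target."""


class UndefinedTestError(OctInflateError):
    """A statistical test is undefined for the given input (e.g. all-zero diffs)."""


class SchemaError(OctInflateError):
    """A table file is missing a required column."""
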