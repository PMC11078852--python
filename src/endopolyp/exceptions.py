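"""Exception hierarchy for the measurement pipeline.

Every failure mode a caller may want to branch on gets its own class; all
inherit from :class:`EndopolypError` so CLI wrappers can catch one type.
"""


class EndopolypError(Exception):
    """Base class for all package errors."""


class GeometryError(EndopolypError):
    """Invalid or degenerate camera/ray geometry."""


class BehindCameraError(GeometryError):
    """A 3D point projects from at or behind the camera plane."""


class DegenerateGeometryError(GeometryError):
    """Ray pair too close to parallel for triangulation."""


class UndistortionError(GeometryError):
    """Iterative undistortion failed to converge."""


class MaskError(EndopolypError):
    """Segmentation mask invalid or empty after refinement."""


class ContourError(EndopolypError):
    """Border contour extraction or resampling failed."""


class ShapeContextError(EndopolypError):
    """Invalid shape-context input (too few points, mismatched bins)."""


class ReconstructionError(EndopolypError):
    """Too few border points survived triangulation."""


class EllipseFitError(EndopolypError):
    """Conic fit degenerated (collinear points, non-ellipse conic)."""


class QualityGateError(EndopolypError):
    """No image pair satisfied the motion-quality recommendations."""


class PoseGenerationError(EndopolypError):
    """Synthetic pose-set constraint satisfaction failed."""


class ConfigError(EndopolypError):
    """Malformed or inconsistent configuration / input files."""


class StatsError(EndopolypError):
    """Invalid input to an agreement-statistics routine."""
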