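"""Exception hierarchy for fastsurf.

All package-specific failures derive from :class:`FastsurfError` so callers
can catch one base class at CLI or pipeline boundaries.
"""


class FastsurfError(Exception):
    """Base class for all fastsurf errors."""


class EmptySegmentation(FastsurfError):
    """Label volume contains no foreground voxels."""


class MultiComponentError(FastsurfError):
    """Foreground is not a single 26-connected component."""


class OpenSurfaceError(FastsurfError):
    """Operation requires a closed (watertight) mesh."""


class InvalidTransform(FastsurfError):
    """Affine transform matrix is singular or malformed."""


class MultiContourSliceError(FastsurfError):
    """A slice intersects the foreground in more than one closed curve
    (multiple components or internal holes); only one contour per slice
    is supported."""


class DegenerateContourError(FastsurfError):
    """Contour has (near-)zero perimeter and cannot be resampled."""


class TooFewContours(FastsurfError):
    """Fewer than the minimum of four contours requested or available."""


class TooManyContours(FastsurfError):
    """More contours requested than occupied slices."""


class ScaffoldError(FastsurfError):
    """Contour stack cannot be assembled into a regular scaffold mesh."""


class GraphError(FastsurfError):
    """Scaffold connectivity graph is invalid (e.g. isolated vertex)."""


class SolverError(FastsurfError):
    """Sparse fairing solve failed to converge, including direct fallback."""


class GridError(FastsurfError):
    """Overlap grid is degenerate (e.g. empty union)."""


class DomainError(FastsurfError):
    """Scalar metric argument outside its mathematical domain."""


class SpecError(FastsurfError):
    """Phantom specification is inconsistent or out of bounds."""
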