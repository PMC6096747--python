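"""Exception hierarchy for tubegeom.

All exceptions derive from :class:`TubegeomError` so callers can catch the
whole family with one clause; the CLI maps each subclass to a categorized
message and a nonzero exit code.
"""


class TubegeomError(Exception):
    """Base class for all tubegeom errors."""


class InvalidContourError(TubegeomError):
    """A contour violates its invariants (e.g. fewer than 3 points)."""


class DegenerateCenterlineError(TubegeomError):
    """Consecutive contour centroids coincide; arc length is undefined."""


class OutOfDomainError(TubegeomError):
    """A query coordinate lies outside the sampled surface domain."""


class ZeroRadiusError(TubegeomError):
    """A boundary point coincides with its contour centroid."""


class NoIntersectionError(TubegeomError):
    """Mother and daughter boundaries have no point pair within tolerance."""


class ProjectionDegenerateError(TubegeomError):
    """A Greenwich propagation direction is parallel to the target plane."""


class DegenerateInputError(TubegeomError):
    """Coincident points handed to a three-point circle fit."""


class GridAlignmentError(TubegeomError):
    """Two fields do not share a common (sigma, theta) grid."""


class CentroidOutsideError(TubegeomError):
    """A chord ray from the centroid does not hit the contour polygon."""


class DegeneratePhantomError(TubegeomError):
    """Phantom parameters produce a self-intersecting surface."""


class NoDataError(TubegeomError):
    """An error summary was requested over an empty node set."""


class ContourFileError(TubegeomError):
    """A contour-set file violates the on-disk schema."""
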