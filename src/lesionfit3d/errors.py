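"""Exception hierarchy.

Every error raised on a violated contract derives from :class:`LesionFitError`
so callers (and the CLI) can catch domain failures without masking bugs.
"""


class LesionFitError(Exception):
    """Base class for all domain errors raised by lesionfit3d."""


class DimensionError(LesionFitError, ValueError):
    """Array or ROI shapes are inconsistent with the voxel grid."""


class EmptyInputError(LesionFitError, ValueError):
    """An operation that needs at least one inside voxel (or row) got none."""


class InsufficientDataError(LesionFitError, ValueError):
    """Too few points/slices to determine the requested quantity."""


class DegenerateGeometryError(LesionFitError, ValueError):
    """Point configuration does not determine a 3D quadric (rank deficiency)."""


class NotAnEllipsoidError(LesionFitError, ValueError):
    """The fitted/supplied quadric is not a real ellipsoid."""


class TruncationError(LesionFitError, ValueError):
    """A phantom extends beyond the voxel grid it should be rasterized on."""


class EmptyPhantomError(LesionFitError, ValueError):
    """A phantom is smaller than a single voxel and rasterizes to nothing."""


class ValidationError(LesionFitError, ValueError):
    """Tabular or parameter input violates its documented contract."""


class FormatError(LesionFitError, ValueError):
    """A file could not be parsed in the declared format."""


class UndefinedStatisticError(LesionFitError, ValueError):
    """The requested statistic is undefined for the given input (e.g. constant data)."""
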