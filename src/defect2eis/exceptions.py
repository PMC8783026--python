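"""Exception hierarchy shared across the package."""


class Defect2EISError(Exception):
    """Base class for all package errors."""


class ValidationError(Defect2EISError):
    """Input data failed validation (bad columns, out-of-field coordinates, ...)."""


class GeometryError(Defect2EISError):
    """Geometric precondition violated (zero-area field, overlapping disks, ...)."""


class InsufficientPointsError(Defect2EISError):
    """Too few points for the requested tessellation or statistic."""


class DegenerateTessellationError(Defect2EISError):
    """Duplicate coordinates make the Voronoi tessellation ill-defined."""


class ParameterError(Defect2EISError):
    """A parameter value is outside its admissible range."""


class NumericalError(Defect2EISError):
    """A numerical solve failed to produce a finite result."""


class NoInteriorMinimumError(Defect2EISError):
    """The admittance-phase curve has no minimum strictly inside the grid."""
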