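"""Exception hierarchy."""


class FacetFitError(Exception):
    """Base class for all package errors."""


class InvalidCellError(FacetFitError):
    """Unit cell metric is singular or out of range."""


class UnboundedShapeError(FacetFitError):
    """The half-space system does not enclose a finite polyhedron."""


class DegenerateShapeError(FacetFitError):
    """Fewer than four effective faces / vertices bound the shape."""


class HabitMismatchError(FacetFitError):
    """Two configurations on different habits were compared."""


class InfeasiblePriorError(FacetFitError):
    """Rejection sampling budget exhausted under the morphology constraints."""


class EmptyObservationError(FacetFitError):
    """All keypoints of a frame were dropped by the noise model."""


class ProjectionError(FacetFitError):
    """Wireframe projection failed."""
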