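"""Exception hierarchy for the bivshape pipeline."""


class BivShapeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BivShapeError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigurationError(BivShapeError, ValueError):
    """A cohort spec or pipeline config violates its invariants."""


class InsufficientDataError(BivShapeError, ValueError):
    """Fewer samples/slices/frames than the operation requires."""


class IncompatiblePopulationError(BivShapeError, ValueError):
    """Meshes or sequences do not share the required topology."""


class NonWatertightError(BivShapeError, ValueError):
    """A surface has boundary edges where a closed surface is required."""


class DegeneratePopulationError(BivShapeError, ValueError):
    """A population with zero total variance cannot be decomposed."""


class DegenerateControlError(BivShapeError, ValueError):
    """Control group has zero spread along a mode; z-scoring undefined."""


class UndefinedCorrelationError(BivShapeError, ValueError):
    """Correlation undefined (constant input or all pairs tied)."""


class UndefinedMetricError(BivShapeError, ValueError):
    """A confusion metric is undefined because a class is absent."""


class SchemaError(BivShapeError, ValueError):
    """A clinical table is missing required columns."""


class ValidationError(BivShapeError, ValueError):
    """A clinical table contains values outside the allowed domain."""


class JoinError(BivShapeError, ValueError):
    """Subject identifiers of two tables/arrays cannot be aligned."""


class GapError(BivShapeError, ValueError):
    """A surface contour is missing on an interior slice."""


class NumericalError(BivShapeError, ArithmeticError):
    """Round-off exceeded the tolerated bound."""
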