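"""Exception hierarchy.

All package errors derive from :class:`LfpCleanError` so callers can catch
one base class; subclasses mark which contract was violated.
"""


class LfpCleanError(Exception):
    """Base class for all lfpclean errors."""


class InvalidWindowError(LfpCleanError):
    """Window geometry is impossible (e.g. window longer than the recording)."""


class InvalidInputError(LfpCleanError):
    """An input vector or group violates a precondition (empty, non-finite...)."""


class InvalidScaleError(LfpCleanError):
    """Scaling factor is zero or non-finite."""


class InvalidEpochError(LfpCleanError):
    """A supplied clean epoch is shorter than one analysis window."""


class GeometryError(LfpCleanError):
    """Segment length is not compatible with the labelling window grid."""


class DimensionError(LfpCleanError):
    """Array shapes disagree with each other or with the window grid."""


class InsufficientDataError(LfpCleanError):
    """Too few segments/examples for the requested operation."""


class InvalidGridError(LfpCleanError):
    """Configuration grid entries are invalid or duplicated."""


class ShapeError(LfpCleanError):
    """Tensor/vector dimensions are inconsistent inside a model."""


class ArchitectureError(LfpCleanError):
    """A network cannot be built with the requested geometry."""


class DivergenceError(LfpCleanError):
    """Training produced a non-finite loss."""


class FitError(LfpCleanError):
    """A linear-model fit failed (singular design, impossible orders...)."""


class PropagationError(LfpCleanError):
    """Recursive forecasting produced a non-finite prediction."""


class ParseError(LfpCleanError):
    """A recording file could not be parsed."""


class BundleVersionError(LfpCleanError):
    """A result bundle was written by an incompatible schema version."""


class ConfigError(LfpCleanError):
    """A pipeline configuration document is invalid."""


class StabilityError(LfpCleanError):
    """Requested synthetic background process is non-stationary."""
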