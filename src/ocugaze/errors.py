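"""Exception hierarchy.

Every error raised by the library derives from :class:`OcugazeError` and carries a
short category name used by the CLI when reporting failures.
"""


class OcugazeError(Exception):
    """Base class for all package errors."""

    category = "error"


class ConfigurationError(OcugazeError):
    """Invalid or missing configuration value."""

    category = "configuration"


class GeometryError(OcugazeError):
    """Geometrically impossible construction (e.g. tumor cap beyond a hemisphere)."""

    category = "geometry"


class FeasibilityError(OcugazeError):
    """Gaze direction outside the clinical polar-angle limit."""

    category = "feasibility"


class TreatabilityError(OcugazeError):
    """Beam parameters violate hardware limits (range or aperture); the candidate
    orientation is clinically untreatable and is discarded by the optimizer."""

    category = "treatability"


class AttributionError_(OcugazeError):
    """A structure could not be attributed to any voxel of the dose grid."""

    category = "attribution"


class ModelError(OcugazeError):
    """Eye model is missing a required structure or is otherwise invalid."""

    category = "model"


class SchemaError(OcugazeError):
    """A serialized file does not validate against the expected schema."""

    category = "schema"


class StateError(OcugazeError):
    """Operation called in an invalid state (e.g. predict before train)."""

    category = "state"


class MapError(OcugazeError):
    """Not enough evaluations to build a continuous gaze map."""

    category = "map"


class OptimizationError(OcugazeError):
    """The optimizer found no treatable candidate orientation."""

    category = "optimization"

    def __init__(self, message, reasons=None):
        super().__init__(message)
        #: per-candidate diagnostic strings, index -> reason
        self.reasons = reasons or {}
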