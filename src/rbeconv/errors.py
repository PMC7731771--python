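"""Exception hierarchy for dose-conversion pipelines."""


class RBEConvError(Exception):
    """Base class for all package errors."""


class GeometryError(RBEConvError):
    """Grids/masks that are not congruent, or structures that do not fit the grid."""


class EmptyStructureError(RBEConvError):
    """A structure with no voxels was used where a non-empty one is required."""

    def __init__(self, name: str):
        self.structure_name = name
        super().__init__(f"structure '{name}' contains no voxels")


class DomainError(RBEConvError, ValueError):
    """An argument outside its mathematical domain (negative dose, volume out of range, ...)."""


class ConfigurationError(RBEConvError):
    """Inconsistent or incomplete configuration (model tags, metrics, organ names, modes)."""


class PipelineError(RBEConvError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
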