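"""Exception hierarchy shared across the package."""


class BeevrError(Exception):
    """Base class for all package-specific errors."""


class InputError(BeevrError, ValueError):
    """Invalid or non-finite input data."""


class GeometryError(BeevrError, ValueError):
    """Invalid geometric quantity (non-positive width/distance, ...)."""


class DegenerateGeometryError(GeometryError):
    """Observer coincident with a stimulus center: bearing undefined."""


class ConfigError(BeevrError, ValueError):
    """Invalid run configuration."""


class SimulationError(BeevrError, RuntimeError):
    """An agent or the trial state machine produced an invalid state."""


class SchemaError(BeevrError, ValueError):
    """A table does not conform to its declared schema."""


class OrderingError(BeevrError, ValueError):
    """A Cq value exceeds the batch maximum it is referenced against."""


class PipelineStageError(BeevrError, RuntimeError):
    """A pipeline stage failed; the stage name is carried in args."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage
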