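"""Exception hierarchy used across the package."""


class ShrubvolError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShrubvolError, ValueError):
    """Invalid generator or run configuration."""


class DomainError(ShrubvolError, ValueError):
    """Input outside the mathematical domain of an operation."""


class GridStateError(ShrubvolError, RuntimeError):
    """A grid operation was requested before the soil reference was set."""


class SoilReferenceError(ShrubvolError, ValueError):
    """The bare-ground mask needed for the soil reference is unusable."""


class SelectionError(ShrubvolError, ValueError):
    """Model selection was requested on an empty set of converged fits."""


class UnsupportedModelError(ShrubvolError, TypeError):
    """Operation not defined for this model family."""


class PipelineStageError(ShrubvolError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
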