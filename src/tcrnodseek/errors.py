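"""Exception hierarchy shared across the package."""


class TcrNodSeekError(Exception):
    """Base class for all package errors."""


class FormatError(TcrNodSeekError, ValueError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(TcrNodSeekError, ValueError):
    """Input data violates a documented invariant."""


class ConfigError(TcrNodSeekError, ValueError):
    """A configuration value is out of range or inconsistent."""


class InsufficientDataError(TcrNodSeekError, ValueError):
    """Not enough observations to run the requested comparison."""


class PipelineStageError(TcrNodSeekError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
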