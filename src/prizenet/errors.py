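"""Exception hierarchy shared across the package."""


class PrizenetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrizenetError, ValueError):
    """An input file or table violates its expected layout or value range."""


class ParameterError(PrizenetError, ValueError):
    """A parameter or configuration value is outside its valid domain."""


class SizeError(ParameterError):
    """An instance is too large for the requested (exact) algorithm."""


class PipelineStageError(PrizenetError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
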