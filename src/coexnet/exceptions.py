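"""Exception hierarchy used across the pipeline."""


class CoexnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoexnetError, ValueError):
    """Invalid simulation or run configuration."""


class ValidationError(CoexnetError, ValueError):
    """Input violates a documented precondition."""


class DegenerateInputError(CoexnetError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero matrix)."""


class FormatError(CoexnetError, ValueError):
    """A file does not match the expected dialect."""


class PipelineError(CoexnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
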