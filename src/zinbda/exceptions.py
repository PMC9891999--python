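"""Exception hierarchy shared across the package."""


class ZinbdaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ZinbdaError, ValueError):
    """A configuration object or argument is invalid."""


class FormatError(ZinbdaError, ValueError):
    """An input file does not conform to the expected layout."""


class ValidationError(ZinbdaError, ValueError):
    """Inputs are well-formed but mutually inconsistent."""


class EmptyTableError(ValidationError):
    """An operation removed every sample (or feature) from a table."""


class DegeneratePartitionError(ValidationError):
    """A log-ratio partition has an empty numerator or denominator set."""


class InitializationError(ZinbdaError, RuntimeError):
    """The sampler could not find a finite starting point."""


class PipelineError(ZinbdaError, RuntimeError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"[stage: {stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
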