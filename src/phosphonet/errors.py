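"""Exception types shared across the pipeline."""


class PhosphonetError(Exception):
    """Base class for all package errors."""


class ConfigError(PhosphonetError):
    """A configuration value violates an invariant; message names the field."""


class MotifParseError(PhosphonetError):
    """Motif library text could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class PipelineError(PhosphonetError):
    """A pipeline stage failed; message names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
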