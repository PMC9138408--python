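"""Exception hierarchy shared across the package.

The pipeline distinguishes configuration mistakes (bad thresholds, impossible
simulation budgets) from malformed input data so the CLI can map them onto
distinct exit codes.
"""


class EtpLineageError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(EtpLineageError, ValueError):
    """Invalid configuration: thresholds, probabilities, or budget overruns."""


class DataFormatError(EtpLineageError, ValueError):
    """Malformed or inconsistent input data (file content or in-memory)."""


class PipelineStageError(EtpLineageError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the root cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
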