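"""Typed exceptions raised across the pipeline.

Every malformed input or configuration produces one of these; nothing is
ever silently dropped or partially loaded.
"""


class BgcrankError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BgcrankError):
    """A configuration object violates its invariants (names the field)."""


class FormatError(BgcrankError):
    """A file does not conform to the canonical TSV dialect."""


class ValidationError(BgcrankError):
    """Parsed data violates a table invariant (cites rows/ids)."""


class ConvergenceError(BgcrankError):
    """Iterative solver failed to reach tolerance; carries last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class PipelineError(BgcrankError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
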