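"""Exception hierarchy.

Every error raised by the package derives from :class:`ScResponseError` so
callers (and the CLI) can distinguish validation, parsing, configuration and
compute failures by exception class.
"""


class ScResponseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScResponseError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(ScResponseError):
    """A data invariant was violated (negative expression, duplicate id, ...)."""


class ParseError(ScResponseError):
    """An on-disk artifact could not be parsed; includes file/line context."""


class ArchitectureError(ScResponseError):
    """Input shape is incompatible with a network's conv/pool cascade."""


class ConvergenceError(ScResponseError):
    """An iterative fit failed to converge (e.g. monotone separation in Cox)."""


class PipelineStageError(ScResponseError):
    """A pipeline stage failed; carries the stage name and a machine code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
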