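"""Exception hierarchy shared across the package."""


class XmiConnectError(Exception):
    """Base class for all package errors."""


class SpecValidationError(XmiConnectError, ValueError):
    """A configuration or cohort specification violates an invariant."""


class DegenerateInputError(XmiConnectError, ValueError):
    """An input is degenerate for the requested computation (constant series,
    zero variance, empty class, ...)."""


class TrainingError(XmiConnectError, RuntimeError):
    """Model training failed (non-finite loss or inconsistent shapes)."""


class StageError(XmiConnectError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
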