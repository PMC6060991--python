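"""Exception hierarchy shared across the pipeline stages."""


class DgeflowError(Exception):
    """Base class for all errors raised by dgeflow."""


class ValidationError(DgeflowError, ValueError):
    """An input value or table violates a stated invariant."""


class ConfigError(DgeflowError, ValueError):
    """A configuration object (simulation or pipeline) is inconsistent."""


class FixtureLookupError(DgeflowError, KeyError):
    """An unknown packaged-fixture name was requested."""


class SetExpressionError(DgeflowError, ValueError):
    """A set-combination expression failed to parse or evaluate.

    Carries the character position of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class StageError(DgeflowError, RuntimeError):
    """A pipeline stage failed; earlier stage outputs are left on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
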