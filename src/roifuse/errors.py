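"""Exception hierarchy shared across the pipeline stages."""


class RoifuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RoifuseError, ValueError):
    """A configuration object violates one of its invariants.

    The message names the offending field.
    """


class DataError(RoifuseError, ValueError):
    """An input table violates the pipeline's data contract."""


class EmptySelectionError(RoifuseError):
    """Feature selection eliminated every feature."""


class StageError(RoifuseError):
    """An experiment stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
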