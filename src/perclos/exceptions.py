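"""Package-specific exception types."""


class PerclosError(Exception):
    """Base class for errors raised by this package."""


class DomainError(PerclosError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class SingularFitError(PerclosError, ValueError):
    """A least-squares fit is singular (e.g. the regressor is constant)."""


class ConfigurationError(PerclosError, ValueError):
    """Inputs are structurally unusable (missing channels, bad config keys)."""


class PipelineError(PerclosError, RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
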