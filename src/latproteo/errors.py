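"""Exception hierarchy shared across the package."""


class LatproteoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LatproteoError):
    """A required column, option or config entry is missing or malformed."""


class DataError(LatproteoError):
    """Input values violate the data contract (negative intensity, p outside [0,1], ...)."""


class DesignError(LatproteoError):
    """The sample design does not match the quantification matrix."""


class ParameterError(LatproteoError):
    """An analysis parameter is out of its admissible range."""


class DegenerateStatisticError(LatproteoError):
    """A statistic is undefined for the given input (e.g. zero moderated variance)."""


class PipelineError(LatproteoError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
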