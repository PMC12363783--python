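"""Exception hierarchy used across the pipeline."""


class InfoconnError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(InfoconnError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedResultError(InfoconnError, ArithmeticError):
    """The requested quantity is mathematically undefined for these inputs."""


class InsufficientDataError(InfoconnError, ValueError):
    """Too few valid observations to compute the requested quantity."""


class NoValidPairsError(InsufficientDataError):
    """A similarity matrix has no valid (cross-run) trial pairs."""


class IllPosedError(InfoconnError, ValueError):
    """A linear model is rank deficient or otherwise ill posed."""


class PipelineStageError(InfoconnError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
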