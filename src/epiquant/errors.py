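"""Exception taxonomy shared by all pipelines."""


class EpiquantError(Exception):
    """Base class for all package errors."""


class InvalidROIError(EpiquantError):
    """An ROI is malformed (too few vertices, open where closed is required, zero area)."""


class InvalidParameterError(EpiquantError):
    """A numeric parameter is out of its documented range."""


class EmptyROIError(EpiquantError):
    """A mask or region that must contain pixels is empty."""


class UndefinedMetricError(EpiquantError):
    """The metric is mathematically undefined for this input (e.g. zero total intensity)."""


class DegenerateThresholdError(EpiquantError):
    """Automatic thresholding is impossible (constant image)."""


class EmptyTraceError(EpiquantError):
    """A membrane trace has no measured columns."""


class PipelineStageError(EpiquantError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
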