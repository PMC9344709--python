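"""Exception hierarchy shared across the pipeline stages."""


class AdcTextureError(ValueError):
    """Base class for all domain errors raised by this package."""


class DegenerateSampleError(AdcTextureError):
    """A statistic is undefined for the given pixel sample (e.g. zero variance)."""


class DegenerateCohortError(AdcTextureError):
    """A simulated cohort is too small to carry both classes."""


class FeatureExtractionError(AdcTextureError):
    """A slice could not yield a complete, valid feature record."""


class PipelineStageError(AdcTextureError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
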