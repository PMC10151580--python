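"""Exception hierarchy for the trans-omics correlation pipeline."""


class TransomicsError(Exception):
    """Base class for all package-specific errors."""


class InsufficientOverlapError(TransomicsError):
    """Fewer than 3 pairwise-complete samples; a correlation is undefined."""


class DegenerateDataError(TransomicsError):
    """Zero variance / zero range: the statistic is undefined on these values."""


class PerfectCorrelationError(TransomicsError):
    """|r| = 1: the t statistic is infinite."""


class CollinearControlError(TransomicsError):
    """A controlled variable is perfectly correlated with x or y."""


class FormatError(TransomicsError):
    """A layer or metadata file violates the expected tabular format."""


class ValidationError(TransomicsError):
    """Metadata values violate their documented constraints."""


class NoCommonSamplesError(TransomicsError):
    """Layer / metadata sample sets have an empty intersection."""


class UnknownReferenceError(TransomicsError):
    """A factor, sample, layer or covariate name does not resolve."""


class PipelineError(TransomicsError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
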