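"""Exception hierarchy used across the pipeline stages."""


class DynconnError(Exception):
    """Base class for all package errors."""


class SchemaError(DynconnError):
    """An input table is missing required columns or has a malformed header."""


class ValidationError(DynconnError):
    """A record violates an invariant (e.g. CRS-R total != sub-score sum)."""


class MontageError(DynconnError):
    """A requested channel label is absent from the montage."""


class ParameterError(DynconnError):
    """A parameter is outside its admissible range."""


class DataError(DynconnError):
    """Input data are non-finite or otherwise unusable."""


class SelectionError(DynconnError):
    """A trial/condition selection matched nothing where >=1 was required."""


class AggregationError(DynconnError):
    """Objects being aggregated have incompatible shapes or metadata."""


class StatisticsError(DynconnError):
    """Too few observations for the requested statistical test."""


class PipelineError(DynconnError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
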