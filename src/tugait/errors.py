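"""Exception hierarchy shared across the pipeline."""


class TugaitError(Exception):
    """Base class for all package-specific errors."""


class RecordingError(TugaitError):
    """A recording violates the data model."""


class MissingSensorError(RecordingError):
    """A required sensor placement is absent."""

    def __init__(self, placement: str):
        self.placement = placement
        super().__init__(f"missing sensor block: {placement!r}")


class TimebaseError(RecordingError):
    """Streams do not share one uniform 100 Hz timebase."""


class RangeError(RecordingError):
    """A sample exceeds the physical range of the sensor."""

    def __init__(self, placement: str, channel: str, axis: str, index: int, value: float):
        self.placement = placement
        self.channel = channel
        self.axis = axis
        self.index = index
        self.value = value
        super().__init__(
            f"out-of-range sample: {placement}.{channel}.{axis}[{index}] = {value:g}"
        )


class FormatError(RecordingError):
    """File content cannot be interpreted as a recording."""


class InvariantError(RecordingError):
    """A domain-type invariant is violated."""


class SchemaError(TugaitError):
    """Tabular inputs do not match the expected schema."""


class ProfileRangeError(TugaitError):
    """A group profile produces non-physical signals."""


class SegmentationError(TugaitError):
    """The TUG trial cannot be partitioned into its phases."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        msg = reason if not detail else f"{reason}: {detail}"
        super().__init__(msg)


class InsufficientCyclesError(TugaitError):
    """Too few gait cycles to compute a per-cycle statistic."""


class FoldError(TugaitError):
    """Cross-validation folds cannot be formed."""


class DegenerateFoldError(TugaitError):
    """A training fold contains a single class."""


class UndefinedMetricError(TugaitError):
    """A metric is undefined for the given inputs."""


class StageError(TugaitError):
    """A pipeline stage failed; carries stage name and artifact context."""

    def __init__(self, stage: str, cause: Exception, context: str = ""):
        self.stage = stage
        self.cause = cause
        self.context = context
        msg = f"stage {stage!r} failed: {cause}"
        if context:
            msg += f" (context: {context})"
        super().__init__(msg)
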