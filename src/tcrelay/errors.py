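"""Exception hierarchy.

All package-specific failures derive from :class:`TcrelayError` so callers
(and the CLI) can distinguish analysis failures from programming errors.
"""


class TcrelayError(Exception):
    """Base class for all tcrelay failures."""


class ParameterError(TcrelayError, ValueError):
    """A supplied parameter violates its documented constraints."""


class TraceValidationError(ParameterError):
    """A trace violates its invariants (non-finite samples, bad rate, ...)."""


class TraceFormatError(TcrelayError):
    """An on-disk trace file does not conform to the dialect."""


class MissingHeaderError(TraceFormatError):
    """A required ``# key=value`` header line is absent."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(f"trace file is missing required header {key!r}")


class EmptyTraceError(TraceFormatError):
    """A trace file has a valid header but no sample lines."""


class GenerationError(TcrelayError):
    """Synthetic-trial generation could not produce a valid trial."""


class StructuralError(TcrelayError):
    """Inputs are structurally inconsistent (e.g. a TS trial with no
    thalamic trace supplied at all — distinct from one where no thalamic
    spike was detected)."""


class SelectionInfeasibleError(TcrelayError):
    """Fewer than the required number of spikes / distinct traces are
    available for representative-spike selection."""


class UndefinedCorrelationError(ParameterError):
    """Pearson correlation is undefined (a constant input)."""


class AlignmentError(TcrelayError):
    """Segment alignment left less than one segment of overlap."""


class PipelineStageError(TcrelayError):
    """Wraps any stage failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
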