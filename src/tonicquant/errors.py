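"""Exception hierarchy for tonicquant.

All validation failures raise :class:`ValidationError` (a ``ValueError``)
naming the offending field, so callers can rely on ``except ValueError``.
"""


class TonicQuantError(Exception):
    """Base class for all tonicquant-specific errors."""


class ValidationError(TonicQuantError, ValueError):
    """An input value violates a documented precondition.

    The message always names the offending field or argument.
    """


class TraceFormatError(TonicQuantError):
    """A trace file violates the dialect (missing header key, wrong units)."""


class TraceParseError(TonicQuantError):
    """A sample line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class InsufficientDataError(TonicQuantError):
    """A recording phase is too short for the requested epochs."""


class FitError(TonicQuantError):
    """A constrained Gaussian fit could not be performed or did not converge.

    ``segment_index`` is set when the failure is tied to a specific epoch.
    """

    def __init__(self, message: str, segment_index: int | None = None):
        super().__init__(message)
        self.segment_index = segment_index


class PipelineError(TonicQuantError):
    """A pipeline stage failed; names the stage and cell involved."""

    def __init__(self, message: str, stage: str = "", cell_id: str = ""):
        super().__init__(message)
        self.stage = stage
        self.cell_id = cell_id
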