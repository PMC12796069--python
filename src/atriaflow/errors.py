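"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`AtriaflowError` so callers (and the
CLI) can map failures to exit codes: segmentation failures are recoverable
data problems, input/format errors are caller mistakes.
"""


class AtriaflowError(Exception):
    """Base class for all package errors."""


class ParameterError(AtriaflowError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ScheduleError(AtriaflowError, ValueError):
    """Frame schedule is overlapping, non-contiguous or inconsistent."""


class FormatError(AtriaflowError, ValueError):
    """An on-disk file does not match the expected layout."""


class GeometryError(AtriaflowError, ValueError):
    """Image grids or geometric specifications are inconsistent."""


class InputError(AtriaflowError, ValueError):
    """In-memory inputs to an operation are inconsistent."""


class StateError(AtriaflowError, RuntimeError):
    """An operation was called before its prerequisites were computed."""


class SegmentationError(AtriaflowError, RuntimeError):
    """A segmentation stage could not produce a usable result.

    Carries a ``diagnostics`` dict with stage-specific scalars to make
    failures on real data debuggable.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
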