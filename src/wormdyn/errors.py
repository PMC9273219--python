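"""Exception hierarchy for wormdyn.

All package-specific failures derive from :class:`WormdynError` so callers can
catch one base class; subclasses distinguish malformed files, invalid metadata,
pathological traces, and empty results.
"""


class WormdynError(Exception):
    """Base class for all wormdyn errors."""


class FormatError(WormdynError):
    """A trace file is structurally malformed (e.g. ragged CSV rows)."""


class MetadataError(WormdynError):
    """Required trial metadata (sampling rate, condition, ...) is missing."""


class ValidationError(WormdynError):
    """A domain invariant is violated (negative fluorescence, bad shapes)."""


class BaselineError(WormdynError):
    """A computed F0 baseline is non-positive; the trace is pathological."""


class UndefinedSNRError(WormdynError):
    """SNR is undefined (zero noise amplitude or zero minimal window power)."""


class OrderingError(WormdynError):
    """Transition events are out of order (an OFF precedes any ON)."""


class EmptyResultError(WormdynError):
    """An aggregation was requested over zero usable inputs."""


class GridMismatchError(WormdynError):
    """Spectral inputs do not share a common frequency grid."""


class DegenerateTrialError(WormdynError):
    """A trial carries no usable activity (e.g. non-positive active value)."""


class SampleSizeError(WormdynError):
    """Too few observations per group for the requested comparison."""
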