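"""Exception and warning hierarchy shared by all exodecode modules."""


class ExodecodeError(Exception):
    """Base class for all errors raised by exodecode."""


class FormatError(ExodecodeError):
    """A trial CSV violates the dataset format contract."""


class MetadataError(ExodecodeError):
    """A JSON sidecar is missing or inconsistent with its CSV."""


class ConsistencyError(ExodecodeError):
    """CSV contents and sidecar metadata disagree (e.g. sampling rate)."""


class LayoutError(ExodecodeError):
    """The on-disk dataset layout is malformed."""


class ProtocolError(ExodecodeError):
    """A label stream deviates from the experimental protocol."""


class TaskMappingError(ExodecodeError):
    """A task name has no target under the requested paradigm."""


class FilterDesignError(ExodecodeError):
    """A filter-bank band cannot be realized at the given sampling rate."""


class TrainingError(ExodecodeError):
    """A model cannot be fitted from the given training data."""


class PredictionError(ExodecodeError):
    """A fitted model cannot score the given features."""


class AlignmentError(ExodecodeError):
    """Two per-epoch sequences that must be aligned have different shapes."""


class EvaluationError(ExodecodeError):
    """A cross-validation run cannot be carried out."""


class ConfigError(ExodecodeError):
    """A run configuration file is invalid; the message names the field."""


class ExodecodeWarning(UserWarning):
    """Base class for all warnings emitted by exodecode."""


class LayoutWarning(ExodecodeWarning):
    """Non-fatal dataset layout irregularity (orphan or stray file)."""


class ProtocolWarning(ExodecodeWarning):
    """Non-fatal protocol irregularity (truncated or dropped window)."""


class EpochWarning(ExodecodeWarning):
    """A window was too short to contribute any epoch."""


class EvaluationWarning(ExodecodeWarning):
    """Non-fatal evaluation irregularity (small sample, skipped window)."""
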