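"""Exception hierarchy shared by all pipeline stages.

Two families matter to callers: :class:`FormatError` (bad input files,
mapped to exit code 2 by the CLI) and :class:`ParameterError` (violated
physical or numerical preconditions, exit code 3).
"""


class TmmError(Exception):
    """Base class for all package errors."""


class FormatError(TmmError):
    """Malformed or unreadable input file (CSV dialect, row count, jitter)."""


class ParameterError(TmmError):
    """A precondition on a parameter or input value is violated."""


class GeometryError(ParameterError):
    """A required geometry field is missing for the declared test mode."""


class NonphysicalDelayError(ParameterError):
    """The measured time offset is too large for the specimen thickness.

    Raised when 1/c_water - delta_t/d <= 0, i.e. the substitution relation
    has no positive speed-of-sound solution.
    """


class DegenerateSignalError(ParameterError):
    """An all-zero (or otherwise featureless) waveform: the cross-correlation
    maximum is undefined."""


class InsufficientDataError(ParameterError):
    """Too few samples fall inside the requested fit window."""


class ConfigurationError(ParameterError):
    """Inconsistent simulation or run configuration."""
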