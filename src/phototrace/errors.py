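"""Exception and warning hierarchy.

Analysis functions raise subclasses of :class:`PhototraceError` for
unrecoverable input problems and emit :class:`QualityWarning` (via the
standard ``warnings`` machinery) for suspicious-but-usable data, so that
pipelines can keep running while recording findings.
"""


class PhototraceError(Exception):
    """Base class for all package errors."""


class MalformedInputError(PhototraceError):
    """A file or array violates a structural invariant (e.g. non-monotonic time)."""


class SchemaError(PhototraceError):
    """A delimited-text file lacks the expected columns."""


class ProtocolError(PhototraceError):
    """A light protocol is inconsistent with the requested operation."""


class CoverageError(PhototraceError):
    """The trace does not span the time window an operation needs."""


class ResolutionError(PhototraceError):
    """Too few samples inside an analysis window."""


class DomainError(PhototraceError):
    """A numeric argument is outside the formula's domain."""


class InconsistencyError(PhototraceError):
    """Two measurements contradict each other (e.g. total flash < PSI-only flash)."""


class ConvergenceError(PhototraceError):
    """An iterative fit failed to converge."""


class DegenerateDataError(PhototraceError):
    """The data carry no usable signal for the requested quantity."""


class QualityWarning(UserWarning):
    """Non-fatal data-quality finding (e.g. Fs exceeding Fm')."""
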