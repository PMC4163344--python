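"""Exception hierarchy shared across the package."""


class CprspecError(Exception):
    """Base class for all package-specific errors."""


class RecordFormatError(CprspecError, ValueError):
    """A time-series CSV file violates the declared dialect."""


class WindowAnalysisError(CprspecError, ValueError):
    """A single analysis window cannot produce a feedback estimate.

    These are expected during normal operation (pauses, sensor dropout);
    session-level analysis converts them into gap markers rather than
    propagating them.
    """


class NoCompressionActivityError(WindowAnalysisError):
    """The window contains no measurable motion (zero variance)."""


class NoPeriodicityError(WindowAnalysisError):
    """No spectral peak above the noise floor in the compression band."""


class InsufficientCompressionsError(WindowAnalysisError):
    """Fewer than two reference compressions fall inside the window."""
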