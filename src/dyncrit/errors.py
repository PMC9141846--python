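"""Exception types shared across the toolkit."""


class DyncritError(Exception):
    """Base class for all package-specific errors."""


class BlowupError(DyncritError):
    """A trajectory left the finite domain; carries the step/time of failure."""

    def __init__(self, message: str, step: int | None = None, time: float | None = None):
        super().__init__(message)
        self.step = step
        self.time = time


class GeometryError(DyncritError):
    """A lattice geometry request is inconsistent (e.g. odd checkerboard extent)."""


class InsufficientSpanError(DyncritError):
    """A recorded trace is too short for the requested summary."""


class UndefinedEntropyError(DyncritError):
    """Spectral entropy requested for a spectrum with zero total power."""


class NoCleanWindowsError(DyncritError):
    """Every window of a fit set was flagged; pooled summaries are undefined."""
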