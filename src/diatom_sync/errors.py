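"""Exception hierarchy shared across the package."""


class DiatomSyncError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DiatomSyncError):
    """A configuration value is missing or inconsistent."""


class ValidationError(DiatomSyncError):
    """An input object violates its invariants."""


class RangeError(DiatomSyncError):
    """A scalar argument is outside its documented domain."""


class AnalysisError(DiatomSyncError):
    """A signal cannot be analyzed (too short, non-uniform, all-invalid)."""


class SpectralFitError(AnalysisError):
    """Gaussian peak fit failed to converge.

    Carries the fit diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
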