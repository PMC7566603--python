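"""Exception types shared across the package."""


class OverlayDEError(Exception):
    """Base class for all package-specific errors."""


class DataError(OverlayDEError, ValueError):
    """Raised when input data violate a structural contract (bad table,
    duplicate identifiers, missing lengths, wrong scale, ...)."""


class FitError(OverlayDEError, RuntimeError):
    """Raised when a distribution fit cannot be performed or fails."""
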