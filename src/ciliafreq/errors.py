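"""Exception hierarchy shared across the package."""


class CiliafreqError(Exception):
    """Base class for all package errors."""


class ValidationError(CiliafreqError, ValueError):
    """Raised when an input violates a documented precondition."""


class ConfigurationError(CiliafreqError, ValueError):
    """Raised when required configuration (e.g. a frame rate) is missing."""


class VideoReadError(CiliafreqError, IOError):
    """Raised when a video file cannot be read or decoded."""
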