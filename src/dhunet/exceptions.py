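"""Typed errors raised across the package."""


class ValidationError(ValueError):
    """An argument violates a documented precondition."""


class ManifestError(OSError):
    """A dataset manifest is missing, malformed, or references absent files."""


class ImageIOError(OSError):
    """An image or mask file cannot be read or has the wrong format."""
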