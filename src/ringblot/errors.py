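"""Exception hierarchy shared across the package."""


class RingblotError(Exception):
    """Base class for all package-specific errors."""


class MaskOutOfBoundsError(RingblotError):
    """Raised when a ring mask placed at a candidate center leaves the image."""


class DegenerateNormalizationError(RingblotError):
    """Raised when the outer-ring mean is zero and the profile cannot be normalized."""


class CropBoundsError(RingblotError):
    """Raised when a requested spot crop extends beyond its membrane image."""
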