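"""Exception types shared across the package."""


class KneeKLError(Exception):
    """Base class for package errors."""


class DegenerateImageError(KneeKLError):
    """Raised when an image carries no usable contrast (e.g. constant intensity)."""


class GeometryError(KneeKLError):
    """Raised when a crop/patch geometry does not fit the image it is applied to."""


class ArchitectureError(KneeKLError):
    """Raised when a branch specification is structurally invalid."""
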