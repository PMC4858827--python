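"""Package-specific exceptions."""


class AneumorphError(Exception):
    """Base class for all package errors."""


class ConstructiveGeometryError(AneumorphError):
    """Implicit-geometry meshing produced a non-manifold or open surface."""


class SegmentationError(AneumorphError):
    """Segmentation produced an empty or unusable mask."""


class ConfigurationError(AneumorphError):
    """Invalid configuration values."""
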