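"""Exception types raised across the package."""


class LumicamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LumicamError):
    """Invalid configuration value or invalid generator state."""


class GeometryError(LumicamError):
    """Degenerate or out-of-domain geometric input."""


class NoRealImageError(GeometryError):
    """Object distance does not produce a real image (u <= f)."""


class PartitionOverflowError(LumicamError):
    """Requested stream partition exceeds the generator period."""


class StreamOverrunError(LumicamError):
    """A worker consumed more random draws than its assigned block."""


class RunawayPhotonError(LumicamError):
    """A packet exceeded the per-photon event cap."""


class MergeError(LumicamError):
    """Partial results with mismatching configuration hashes."""
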