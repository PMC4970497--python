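"""Exception hierarchy shared across the package."""


class EmcspiError(Exception):
    """Base class for all package errors."""


class ConfigError(EmcspiError, ValueError):
    """Invalid or incomplete configuration."""


class FormatError(EmcspiError, ValueError):
    """Malformed detector, quaternion or photon file."""


class GeometryError(EmcspiError, ValueError):
    """Detector/model geometry inconsistency (e.g. rotated pixel off-grid)."""


class AliasingError(EmcspiError, ValueError):
    """Particle support too large for the requested reciprocal-space grid."""
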