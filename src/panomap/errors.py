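"""Exception hierarchy shared across the toolkit."""


class PanomapError(Exception):
    """Base class for all toolkit errors."""


class GeometryError(PanomapError):
    """Degenerate ellipsoid, off-surface query, disconnected mesh, ..."""


class PackingError(GeometryError):
    """Requested sensor count cannot be packed at the requested pitch."""


class ProjectionError(GeometryError):
    """Projection undefined at the queried point (e.g. on the polar axis)."""


class TraceError(PanomapError):
    """Malformed or insufficient time-series input."""


class MetricsError(PanomapError):
    """Signal quantification failed (saturation, zero noise window, ...)."""


class MappingError(PanomapError):
    """Activation-map construction or conduction fitting failed."""


class FluorometryError(PanomapError):
    """Inconsistent fluorescence budget."""


class ConfigError(PanomapError):
    """Invalid or unknown configuration keys/values."""


class IOFormatError(PanomapError):
    """File does not conform to a documented schema."""
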