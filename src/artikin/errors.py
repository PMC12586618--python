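"""Exception hierarchy shared across the pipeline stages."""


class ArtikinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArtikinError):
    """Invalid or incomplete configuration / metadata."""


class GeometryError(ArtikinError):
    """Measurement-line geometry violated (out of bounds, degenerate landmarks,
    trajectory exceeding line capacity)."""


class SegmentationError(ArtikinError):
    """Grey-value segmentation cannot proceed (degenerate intensity spread)."""


class ModelError(ArtikinError):
    """Statistical model cannot be fitted (singular design, empty group)."""
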