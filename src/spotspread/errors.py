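"""Exception hierarchy.

All spotspread errors derive from :class:`SpotspreadError` so callers can
catch the package's failures with a single except clause while still
distinguishing configuration mistakes from data problems.
"""


class SpotspreadError(Exception):
    """Base class for all package errors."""


class InputError(SpotspreadError):
    """Invalid input data (missing folder, shape mismatch, bad geometry)."""


class ConfigurationError(SpotspreadError):
    """Invalid configuration (bad pattern, missing role/condition mapping)."""


class DataIntegrityError(SpotspreadError):
    """Inconsistent data (duplicate plate coordinates, spot outside cell)."""


class ImageIOError(SpotspreadError):
    """Failure reading or writing an image or table file."""


class GraphError(SpotspreadError):
    """Invalid workflow graph (cycle, unknown slot, unwired input)."""


class KindMismatchError(GraphError):
    """Edge connects slots of incompatible data kinds."""
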