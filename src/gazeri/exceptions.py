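"""Exception hierarchy.

All errors raised by this package derive from :class:`GazeriError`, so callers
can catch one type at pipeline boundaries while tests assert on the precise
subclass.
"""


class GazeriError(Exception):
    """Base class for all package errors."""


class ParameterError(GazeriError, ValueError):
    """An option or parameter is outside its documented range."""


class GeometryError(GazeriError, ValueError):
    """Array shape or coordinate geometry does not match the grid."""


class DegenerateMapError(GazeriError, ValueError):
    """A feature map is identically zero and cannot be density-normalized."""


class UndefinedMapError(GazeriError, ValueError):
    """A map was requested for a frame where it is undefined (e.g. motion on frame 0)."""


class FormatError(GazeriError, ValueError):
    """An external file does not have the expected layout or contains NaNs."""


class InputError(GazeriError, ValueError):
    """Tabular input violates a contract (empty collection, bad columns, ...)."""


class NoDataError(GazeriError, ValueError):
    """Too few gaze samples to carry out an estimation step."""
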