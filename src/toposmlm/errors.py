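"""Exception hierarchy shared across the package."""


class TopoSMLMError(Exception):
    """Base class for all package errors."""


class DetectionFormatError(TopoSMLMError):
    """A detection table is missing a mapped column or is otherwise malformed."""


class DetectionParseError(TopoSMLMError):
    """A row of a detection table could not be parsed.

    Carries the 1-based data-row number in ``row``.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class MissingFieldError(TopoSMLMError):
    """An operation requires an optional detection field that is absent."""


class ParameterError(TopoSMLMError):
    """A parameter is outside its valid range."""


class ConfigurationError(TopoSMLMError):
    """A scenario or pipeline configuration is inconsistent."""


class DegenerateGeometryError(TopoSMLMError):
    """The point cloud is too degenerate for the requested geometry (e.g. all
    points collinear for a Voronoi tessellation)."""


class DataError(TopoSMLMError):
    """Detection data violates a contract (e.g. negative uncertainty)."""
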