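"""Exception hierarchy for the scale-morphometrics pipeline.

Every error raised by the library derives from :class:`ScalemorphError`, so
drivers can catch one type at the pipeline boundary and attach stage names.
"""


class ScalemorphError(Exception):
    """Base class for all library errors."""


class SchemaError(ScalemorphError):
    """A required column or variable is missing or unresolvable."""


class IntegrityError(ScalemorphError):
    """Duplicate identifiers or inconsistent record structure."""


class MalformedValueError(ScalemorphError):
    """Non-numeric or non-finite cells; carries (row, column) locations."""

    def __init__(self, message: str, locations=None):
        super().__init__(message)
        self.locations = list(locations or [])


class FormatError(ScalemorphError):
    """A landmark or config file does not follow its declared dialect."""


class GeometryError(ScalemorphError):
    """Degenerate landmark configuration (coincident defining points)."""


class DataError(ScalemorphError):
    """Non-finite or otherwise unusable measurement values."""


class DegenerateVariableError(ScalemorphError):
    """A candidate variable has zero variance."""


class InsufficientDataError(ScalemorphError):
    """Too few complete records for the requested computation."""


class UndefinedRatioError(ScalemorphError):
    """A ratio denominator (L5 or L6) is zero."""


class SingularityError(ScalemorphError):
    """Pooled within-group scatter is singular; ridge regularization advised."""


class MapLookupError(ScalemorphError):
    """Unknown squamation area or morphotype id; lists valid ids."""


class ConstructionError(ScalemorphError):
    """Geometrically impossible landmark-template request."""
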