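"""Exception hierarchy shared across the package."""


class FemoffsetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FemoffsetError):
    """An input file does not conform to the expected schema (e.g. missing column)."""


class ValidationError(FemoffsetError):
    """A value violates a domain invariant (unknown role, too few points, ...)."""


class DegenerateGeometryError(FemoffsetError):
    """A fit is undefined for the given points (coincident, collinear, ...)."""
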