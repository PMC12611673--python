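"""Exception hierarchy shared across the package.

All errors derive from :class:`PlatefitError` so callers (and the CLI) can
catch one base class; the subclasses mirror the failure surfaces of the
pipeline: file format, parameterisation, and geometric degeneracy.
"""


class PlatefitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlatefitError, ValueError):
    """A file could not be parsed (malformed STL, bad XYZ token, ...)."""


class ParameterError(PlatefitError, ValueError):
    """An argument is outside its documented range."""


class GeometryError(PlatefitError, ValueError):
    """The geometry is degenerate for the requested operation
    (zero-area mesh, collinear correspondences, coplanar TPS control
    points, ...)."""


class SelectionError(PlatefitError, ValueError):
    """Control-point selection could not satisfy its constraints."""

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable
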