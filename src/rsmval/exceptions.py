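"""Exception hierarchy for rsmval.

All rsmval-specific failures derive from :class:`RsmvalError` so callers can
catch the package's errors with a single except clause while still
distinguishing argument problems (``ValueError`` subclasses) from structural
ones.
"""


class RsmvalError(Exception):
    """Base class for all rsmval errors."""


class UnsupportedDesignError(RsmvalError, ValueError):
    """Requested experimental design is outside the supported family."""


class SingularDesignError(RsmvalError, ValueError):
    """Model matrix is rank deficient; the quadratic surface cannot be fitted."""


class DegenerateSurfaceError(RsmvalError, ValueError):
    """Quadratic surface has a singular Hessian; no isolated stationary point.

    Carries ``null_direction``, a unit vector along which the curvature
    vanishes.
    """

    def __init__(self, message: str, null_direction=None):
        super().__init__(message)
        self.null_direction = null_direction


class SchemaError(RsmvalError, ValueError):
    """Delimited input does not match the expected column schema."""


class EmptyTableError(RsmvalError, ValueError):
    """Input file parsed correctly but contains no data rows."""


class DependencyError(RsmvalError, ValueError):
    """A pipeline stage was requested without the inputs it needs."""
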