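"""Exception hierarchy shared across the package."""


class SCDOTError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SCDOTError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(SCDOTError, ValueError):
    """A point or optode lies outside the mesh, or a mesh is malformed."""


class DimensionError(SCDOTError, ValueError):
    """Array shapes or link tables do not match."""


class NumericalError(SCDOTError, RuntimeError):
    """A linear solve failed or produced an unacceptable residual."""


class NoCornerError(SCDOTError, RuntimeError):
    """The L-curve has no point of positive curvature (no elbow)."""


class ConfigError(SCDOTError, ValueError):
    """A run configuration file is missing a key or holds an invalid value."""
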