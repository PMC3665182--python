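"""Exception hierarchy shared across the package."""


class MacpsoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MacpsoError, ValueError):
    """A parameter violates its documented constraint."""


class InvalidSpecError(InvalidParameterError):
    """A synthetic-image specification is unsatisfiable."""


class OutOfDomainError(MacpsoError, ValueError):
    """A continuous coordinate falls outside the image domain."""


class NoEdgesError(MacpsoError, RuntimeError):
    """Edge detection produced an empty edge map; a distance map cannot be built."""


class InvalidOriginError(InvalidParameterError):
    """The polar origin lies outside the image."""


class InvalidInitializationError(InvalidParameterError):
    """An initial contour leaves the image domain."""


class ShapeMismatchError(MacpsoError, ValueError):
    """Two masks that must share dimensions do not."""


class UndefinedMetricError(MacpsoError, ValueError):
    """A similarity metric is undefined for the given (empty) inputs."""


class InvalidStackError(MacpsoError, ValueError):
    """A contour stack cannot be triangulated (mismatched snaxel counts)."""
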