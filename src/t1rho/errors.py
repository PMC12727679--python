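"""Exception hierarchy for the t1rho package.

All package-raised errors derive from :class:`T1rhoError` so callers can
catch them with a single ``except`` clause; the subclasses mirror the
contract violations of the public API (invalid parameters, degenerate
inputs, grid/format mismatches).
"""


class T1rhoError(Exception):
    """Base class for all t1rho errors."""


class InvalidParameterError(T1rhoError, ValueError):
    """A physical parameter is outside its valid domain (e.g. T1 <= 0)."""


class InsufficientDataError(T1rhoError, ValueError):
    """Too few samples to perform the requested computation."""


class GeometryError(T1rhoError, ValueError):
    """Phantom geometry is inconsistent (e.g. tumour outside the brain)."""


class GridError(T1rhoError, ValueError):
    """Two grids that must share FOV / slice structure do not."""


class EmptyRoiError(T1rhoError, ValueError):
    """An ROI contains no usable voxels."""


class ConfigurationError(T1rhoError, ValueError):
    """Required configuration (e.g. tissue-class T1/T2) is missing."""


class FormatError(T1rhoError, IOError):
    """A file on disk does not satisfy the expected on-disk contract."""
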