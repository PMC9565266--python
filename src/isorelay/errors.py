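"""Exception types shared across the pipeline stages."""


class IsorelayError(Exception):
    """Base class for all package errors."""


class VariableMappingError(IsorelayError, KeyError):
    """A required logical field could not be resolved to a file variable."""


class GeometryError(IsorelayError, ValueError):
    """Grid shapes, thicknesses or masks are inconsistent."""


class TimeOrderingError(IsorelayError, ValueError):
    """Snapshot times are not strictly increasing."""


class ClosureError(IsorelayError, RuntimeError):
    """A budget that must close by construction failed to, indicating
    inconsistent input (fluxes not matching the recorded state evolution)."""


class RegionError(IsorelayError, ValueError):
    """A region specification is invalid or not closed as required."""


class ConfigError(IsorelayError, ValueError):
    """A pipeline or generator configuration failed validation."""
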