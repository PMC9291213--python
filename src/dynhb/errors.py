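"""Exception hierarchy shared across the package."""


class DynHBError(Exception):
    """Base class for all package-specific errors."""


class InputError(DynHBError):
    """Missing, empty or unreadable input."""


class FormatError(DynHBError):
    """A file exists but violates its expected format."""


class StateError(DynHBError):
    """An operation was called on an object in the wrong state."""


class GeometryError(DynHBError):
    """Degenerate or non-physical molecular geometry."""


class ConfigError(DynHBError):
    """Unknown option or inconsistent configuration."""


class CalibrationError(DynHBError):
    """Electrostatic-potential window unusable for fitting a linear map."""


class ConsistencyError(DynHBError):
    """Mismatched shapes, schemas or identifiers between paired inputs."""


class ParameterError(DynHBError):
    """Non-physical force-field parameters."""


class DegenerateTargetError(DynHBError):
    """Response vector has no variance; regression metrics undefined."""


class InsufficientDataError(DynHBError):
    """Too few observations for the requested statistic."""
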