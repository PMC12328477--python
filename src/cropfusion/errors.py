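"""Exception hierarchy shared across the package."""


class CropFusionError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CropFusionError, ValueError):
    """An input violates a documented precondition."""


class RasterFormatError(CropFusionError, IOError):
    """A raster file or its sidecar metadata is malformed or inconsistent."""


class RoleLookupError(CropFusionError, KeyError):
    """A requested band role is not declared on the raster."""


class DegenerateInputError(CropFusionError, ValueError):
    """The input is formally valid but carries no usable signal
    (e.g. zero-variance panchromatic band, all-zero distances)."""


class ConfigurationError(CropFusionError, ValueError):
    """A scene or run configuration is internally inconsistent."""


class CapabilityError(CropFusionError, RuntimeError):
    """An optional backend was requested but its library is not installed."""
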