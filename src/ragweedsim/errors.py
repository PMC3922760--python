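"""Exception types shared across the package."""


class RagweedSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RagweedSimError, ValueError):
    """Invalid parameter values, malformed site descriptors or bad config files."""


class InputError(RagweedSimError, ValueError):
    """Physically invalid runtime inputs (e.g. tmax < tmin, negative rain)."""


class UnsupportedLatitudeError(RagweedSimError, ValueError):
    """Polar latitudes where the day-length geometry is not handled."""


class SimulationStateError(RagweedSimError, RuntimeError):
    """Operation applied to a plant state that cannot accept it (dead/terminated)."""
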