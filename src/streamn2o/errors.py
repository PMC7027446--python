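"""Exception types shared across the package."""


class StreamN2OError(Exception):
    """Base class for all package errors."""


class RangeError(StreamN2OError, ValueError):
    """An input is outside the validity range of a fitted function."""


class ValidationError(StreamN2OError, ValueError):
    """A value or record violates a physical or schema invariant."""


class ConfigurationError(StreamN2OError, ValueError):
    """A configuration file or mapping is incomplete or inconsistent."""
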