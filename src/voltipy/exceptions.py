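"""Exception hierarchy shared across the package."""


class VoltipyError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VoltipyError):
    """A required column is missing or a file does not match the expected schema."""


class ConfigError(VoltipyError):
    """An invalid configuration value (bad generation count, empty taxa list, ...)."""


class InsufficientDataError(VoltipyError):
    """Too few records/weeks/years to compute the requested quantity."""
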