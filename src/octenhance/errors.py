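"""Exception hierarchy shared across the package."""


class OctEnhanceError(Exception):
    """Base class for all package errors."""


class ConfigError(OctEnhanceError, ValueError):
    """Invalid configuration or parameter value."""


class InputError(OctEnhanceError, ValueError):
    """Invalid runtime input (image, table, dataset)."""


class ConstructionError(OctEnhanceError, ValueError):
    """Network cannot be built from the given spec."""


class DegenerateInputError(InputError):
    """Statistically degenerate input (zero variance, all-tied differences)."""
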