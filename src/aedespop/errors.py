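"""Exception hierarchy shared across the package."""


class AedespopError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AedespopError, ValueError):
    """Inconsistent or invalid simulation / kernel configuration."""


class RegistryError(AedespopError, KeyError):
    """Unknown species, unknown event, or malformed parameter registry."""


class FormatError(AedespopError, ValueError):
    """Unparsable or structurally invalid input table."""


class UnsupportedLatitudeError(AedespopError, ValueError):
    """Latitude outside the supported band (|lat| <= 66.5 degrees)."""


class NoDiapauseError(AedespopError, ValueError):
    """Diapause machinery requested for a species without a diapause block."""
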