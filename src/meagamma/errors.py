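"""Exception hierarchy shared across the package."""


class MeaGammaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MeaGammaError):
    """Invalid simulation or run configuration."""


class ParameterError(MeaGammaError):
    """Invalid argument to an analysis operation."""


class FormatError(MeaGammaError):
    """Malformed on-disk container; the message names the missing component."""


class UndefinedKineticsError(MeaGammaError):
    """A kinetic quantity (onset/offset time) is undefined for the given data."""


class ModelError(MeaGammaError):
    """Mixed-model specification or estimability problem."""
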