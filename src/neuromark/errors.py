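"""Exceptions shared across the package."""


class NeuromarkError(ValueError):
    """Base class for all package-specific errors."""


class InsufficientDataError(NeuromarkError):
    """Too few usable observations for the requested statistic."""


class DegenerateInputError(NeuromarkError):
    """Input has no variation where variation is required (constant vector etc.)."""


class ConfigurationError(NeuromarkError):
    """Invalid or inconsistent configuration / study design."""


class FixtureError(NeuromarkError):
    """A packaged data fixture failed its integrity check."""
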