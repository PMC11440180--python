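"""Exception types raised across the package."""


class SpecflimError(Exception):
    """Base class for all specflim errors."""


class ConfigurationError(SpecflimError, ValueError):
    """Invalid instrument, basis or run configuration."""


class DimensionError(SpecflimError, ValueError):
    """Array shapes inconsistent with the declared axes."""


class DomainError(SpecflimError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


class InsufficientSignalError(SpecflimError, ValueError):
    """Too few photons to attempt a fit."""


class FormatError(SpecflimError, ValueError):
    """A file does not conform to the expected container schema."""
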