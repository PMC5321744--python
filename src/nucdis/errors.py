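"""Exception hierarchy shared across the package."""


class NucdisError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NucdisError, ValueError):
    """A configuration value violates its documented constraints."""


class FormatError(NucdisError, ValueError):
    """An input file does not conform to its declared format."""


class ValidationError(NucdisError, ValueError):
    """Structurally valid input violates a semantic precondition."""
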