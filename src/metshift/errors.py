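"""Exception hierarchy shared across the pipeline stages."""


class MetshiftError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetshiftError):
    """Input file does not follow the expected delimited-text layout."""


class ValidationError(MetshiftError):
    """Input parses but violates a domain invariant."""


class DomainError(MetshiftError):
    """An argument is outside the operation's domain."""


class ConfigurationError(MetshiftError):
    """Inconsistent or incomplete configuration."""
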