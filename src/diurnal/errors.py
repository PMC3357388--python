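"""Exception hierarchy shared across the package."""


class DiurnalError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DiurnalError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(DiurnalError):
    """Input data violates a documented precondition or invariant."""


class ConfigError(DiurnalError):
    """An analysis or generator configuration value is invalid."""
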