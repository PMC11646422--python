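"""Exception hierarchy shared across the package."""


class AlgafuelError(Exception):
    """Base class for all package errors."""


class NotationParseError(AlgafuelError, ValueError):
    """A fatty-acid shorthand string could not be parsed."""


class ValidationError(AlgafuelError, ValueError):
    """A domain object violates one of its invariants."""


class DomainError(AlgafuelError, ValueError):
    """An operation was called outside its mathematical domain."""


class ConfigurationError(AlgafuelError, ValueError):
    """A configuration value (standard name, salinity key, ...) is unknown."""
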