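"""Exception hierarchy shared across the pipeline."""


class CrowdvalError(Exception):
    """Base class for all package errors."""


class ParseError(CrowdvalError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CrowdvalError):
    """Data violated a structural invariant (offsets, duplicates, overlaps)."""


class ConfigurationError(CrowdvalError):
    """An argument or configuration value is out of its allowed range."""


class UndefinedAgreementError(CrowdvalError):
    """Agreement coefficient is undefined (e.g. all ratings in one category)."""
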