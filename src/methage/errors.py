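"""Exception hierarchy shared across the toolkit."""


class MethageError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MethageError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(MethageError):
    """In-memory data violates a domain invariant (range, uniqueness, ...)."""


class ConfigurationError(MethageError):
    """A configuration field is outside its permitted range."""


class HarmonizationError(MethageError):
    """A probe panel cannot be reconciled with a matrix under the policy."""


class DegenerateTargetError(MethageError):
    """The regression target carries no information (e.g. constant ages)."""
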