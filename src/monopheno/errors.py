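"""Exception hierarchy shared across the package."""


class MonophenoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MonophenoError):
    """A configuration object is internally inconsistent or incomplete."""


class ValidationError(MonophenoError):
    """An input value violates a documented precondition."""


class FormatError(MonophenoError):
    """A table or file does not conform to the documented schema."""


class InsufficientDataError(MonophenoError):
    """Too few events/objects to evaluate the operation reliably."""
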