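"""Exception hierarchy shared across the package."""


class MRScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRScreenError):
    """A config file, column map or parameter set is unusable."""


class DataError(MRScreenError):
    """Input data violate a structural requirement (duplicates, bad LD matrix, ...)."""


class DomainError(MRScreenError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""
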