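"""Exception hierarchy shared across the package."""


class SubdosError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SubdosError, ValueError):
    """A numeric argument violates its physical or mathematical domain."""


class InvalidStateError(SubdosError, KeyError):
    """An unknown Markov-state label was supplied."""


class ConfigurationError(SubdosError, ValueError):
    """A configuration file or flag set cannot be resolved to a model."""


class NumericalError(SubdosError, ArithmeticError):
    """A numerical routine left its guaranteed-convergence regime."""
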