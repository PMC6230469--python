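"""Exception hierarchy used across the package."""


class PseudorankError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PseudorankError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(PseudorankError):
    """The data admit no meaningful answer (e.g. all cells identical)."""


class NumericalError(PseudorankError):
    """A numerical routine failed beyond recoverable tolerance."""


class ConfigurationError(PseudorankError):
    """A run configuration is inconsistent or incomplete."""


class ContractViolationError(PseudorankError):
    """An operation was invoked outside its allowed phase."""
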