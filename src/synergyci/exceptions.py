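"""Exception hierarchy for synergyci."""


class SynergyCIError(Exception):
    """Base class for all package errors."""


class FittingError(SynergyCIError):
    """A dose-effect fit is infeasible or failed to converge."""


class DesignError(SynergyCIError):
    """A constant-ratio combination design is invalid."""


class DomainError(SynergyCIError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(SynergyCIError):
    """An analysis configuration is inconsistent or incomplete."""
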