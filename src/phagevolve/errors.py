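"""Exception hierarchy shared across the package."""


class PhagevolveError(Exception):
    """Base class for all package errors."""


class DomainError(PhagevolveError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ConfigError(PhagevolveError, ValueError):
    """A configuration file or parameter set is invalid."""


class IntegrationError(PhagevolveError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class UndefinedFrequencyError(DomainError):
    """Genotype frequencies requested for an empty host population."""


class UndefinedCoefficientError(DomainError):
    """Selection coefficient requested while an allele class is absent."""


class InconsistentAssayError(DomainError):
    """A streak-assay result that no resistance phenotype can produce."""


class FitFailureError(PhagevolveError, RuntimeError):
    """All optimiser starts failed to converge."""
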