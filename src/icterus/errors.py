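"""Exception and warning types shared across the package."""


class IcterusError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IcterusError):
    """A config object violates its own invariants (bad sizes, signs, ranges)."""


class DegenerateReferenceError(IcterusError):
    """The white reference patch has a zero channel mean; gains are undefined."""


class EmptyRoIError(IcterusError):
    """A region-of-interest mask selects no pixels."""


class ContractViolationError(IcterusError):
    """An input does not match the contract a model or operation declares."""


class UndefinedAUCError(IcterusError):
    """AUC requested with only one class present."""


class UndefinedMetricError(IcterusError):
    """A confusion-matrix metric has a zero denominator."""


class ZeroVarianceError(IcterusError):
    """Regression requested on predictions with no variance."""


class ContractViolationWarning(UserWarning):
    """Soft contract breach, e.g. white-balancing an already balanced image."""
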