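"""Exception hierarchy for the kinetics/colocalization toolkit."""


class GtpaseKinError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GtpaseKinError, ValueError):
    """A parameter or array violates a precondition (sign, length, range)."""


class PseudoFirstOrderError(InvalidInputError):
    """Protein is not in sufficient excess over the fluorescent reporter.

    The observed-rate model k_obs = k_on*[protein] + k_off is only valid
    when the protein concentration greatly exceeds the reporter, so the
    free-protein concentration stays effectively constant during binding.
    """


class ModeMismatchError(InvalidInputError):
    """A trace's direction contradicts the requested fit (rise vs decay)."""


class UndefinedAffinityError(GtpaseKinError):
    """K_d = k_off/k_on is undefined because no association was observed."""


class PlacementError(GtpaseKinError):
    """Synthetic object placement could not satisfy separation constraints."""


class TraceFormatError(GtpaseKinError, ValueError):
    """A trace/time-course file is malformed (header, rows, monotonicity)."""


class UndefinedStatisticError(GtpaseKinError):
    """An image statistic is undefined (zero variance or empty channel)."""
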