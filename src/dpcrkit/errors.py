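"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation problems (InputError,
ConfigurationError) -> 2, numerical failures (SaturationError,
NumericalError, DetectionFailure) -> 3.
"""


class DpcrKitError(Exception):
    """Base class for all package errors."""


class InputError(DpcrKitError, ValueError):
    """Invalid input data (counts, CSV rows, mismatched identifiers)."""


class ConfigurationError(DpcrKitError, ValueError):
    """Invalid or inconsistent panel / model configuration."""


class SaturationError(DpcrKitError, ArithmeticError):
    """All droplets positive in a required channel: the Poisson estimator
    diverges and the concentration is unquantifiable at this dilution."""


class NumericalError(DpcrKitError, ArithmeticError):
    """Solver or optimiser failure with diagnostics attached."""


class DetectionFailure(DpcrKitError, ArithmeticError):
    """No dilution level rises above the limit of blank."""
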