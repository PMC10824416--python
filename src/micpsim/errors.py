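"""Exception types shared across the package."""


class MicpError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MicpError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConfigurationError(MicpError, ValueError):
    """A scenario/boundary configuration is inconsistent or incomplete."""


class DegenerateFitError(MicpError, ValueError):
    """A regression problem has too few distinct abscissae to be solvable."""


class StabilityError(MicpError, RuntimeError):
    """An explicit step was requested beyond the admissible step size.

    Attributes
    ----------
    admissible_dt : float
        The largest step size (s) the scheme accepts for the current state.
    """

    def __init__(self, message: str, admissible_dt: float):
        super().__init__(message)
        self.admissible_dt = admissible_dt


class UndefinedMetricError(MicpError, ZeroDivisionError):
    """A relative metric is undefined (zero reference value)."""
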