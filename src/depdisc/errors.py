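"""Exception hierarchy for depdisc."""


class DepDiscError(Exception):
    """Base class for all depdisc errors."""


class InvalidGeometryError(DepDiscError, ValueError):
    """A geometric parameter is non-physical (non-positive length, inverted radii, ...)."""


class DomainError(DepDiscError, ValueError):
    """An argument lies outside the mathematical domain of a formula."""


class InfeasibleDesignError(DepDiscError, ValueError):
    """The requested design point cannot be reached (e.g. target resonance above the bare tank's)."""


class FitError(DepDiscError, RuntimeError):
    """A calibration fit could not be performed or did not converge."""


class SolverError(DepDiscError, RuntimeError):
    """A numerical solver failed to reach its convergence criterion."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class OutOfDomainError(DepDiscError, ValueError):
    """A query point lies outside the solved/valid spatial domain."""


class ConfigError(DepDiscError, ValueError):
    """A configuration file failed validation.

    ``field`` carries the dotted path of the offending key (e.g. ``electrodes.gap_m``).
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message if field is None else f"{field}: {message}")
        self.field = field
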