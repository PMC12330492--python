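"""Exception and warning types shared across the package."""


class PermweightError(Exception):
    """Base class for all package-specific errors."""


class SingularFitError(PermweightError):
    """A least-squares problem is degenerate (e.g. all abscissae equal)."""


class NoTransitionError(PermweightError):
    """A titration curve shows no transition, so a pKa cannot be fitted."""


class ConfigError(PermweightError):
    """Inconsistent or invalid run configuration."""


class WeightConservationError(PermweightError):
    """Total walker weight drifted beyond tolerance during a WE run."""


class UndefinedRateError(PermweightError):
    """A rate is requested from a run with no occupancy of the relevant state."""


class StabilityWarning(UserWarning):
    """The integration time step is large enough to degrade bin-scale accuracy."""


class OverflowBinWarning(UserWarning):
    """A walker lies beyond the outermost bin boundary and was clamped."""
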