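"""Exception hierarchy for the hermetia package."""


class HermetiaError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HermetiaError, ValueError):
    """A parameter set violates its invariants (e.g. thresholds out of order)."""


class DomainError(HermetiaError, ValueError):
    """An input lies outside the physical domain of a rate function."""


class DataError(HermetiaError, ValueError):
    """A dataset is malformed or unusable (wrong columns, empty, degenerate)."""


class IntegrationError(HermetiaError, RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


class FitError(HermetiaError, RuntimeError):
    """No multistart run of a least-squares fit converged."""
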