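"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """A grid, schedule, or run configuration violates its invariants."""


class SolverError(RuntimeError):
    """The sparse linear solver failed to meet its residual contract."""


class MassBalanceError(RuntimeError):
    """Cumulative boundary influx and integrated mass disagree beyond tolerance."""


class InsufficientDataError(ValueError):
    """A derived quantity was requested without the inputs it needs."""


class CoverageError(ValueError):
    """A master curve does not span the dimensionless times implied by the data."""
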