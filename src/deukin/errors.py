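"""Exception hierarchy shared by all deukin modules."""


class DeukinError(Exception):
    """Base class for all errors raised by deukin."""


class ParameterError(DeukinError, ValueError):
    """A model parameter violates its constraints (e.g. d2 <= p2)."""


class ConfigurationError(DeukinError, ValueError):
    """An enrichment schedule, chain spec or run config is inconsistent."""


class DomainError(DeukinError, ValueError):
    """An evaluation was requested outside the valid domain (e.g. t < 0)."""


class DataError(DeukinError, ValueError):
    """Observed/simulated time-series data are malformed or insufficient."""


class FitError(DeukinError, RuntimeError):
    """All optimizer starts failed to converge."""
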