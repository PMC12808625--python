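"""Exception hierarchy for cfglucose."""


class CFGlucoseError(Exception):
    """Base class for all cfglucose errors."""


class DomainError(CFGlucoseError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(CFGlucoseError, ValueError):
    """A configuration value violates the schema or an invariant."""


class DivergenceError(CFGlucoseError, RuntimeError):
    """A computation aborted because a trajectory blew up.

    Carries whatever partial result was available at the time of failure in
    :attr:`partial`.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
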