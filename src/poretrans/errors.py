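"""Exception types shared across the package."""


class PoretransError(Exception):
    """Base class for all package errors."""


class OverlapError(PoretransError):
    """Two particles coincide; a divergent pair potential was requested."""


class PackingError(PoretransError):
    """Random insertion failed to place particles without overlap."""


class InstabilityError(PoretransError):
    """Integration produced a per-step displacement larger than 0.5 sigma.

    Usually means the timestep is too large for the stiffest interaction
    present, or particles were initialised inside a repulsive core.
    """


class ConfigError(PoretransError):
    """Invalid or unknown configuration key/value.

    Attributes
    ----------
    key : str
        The offending configuration key, when identifiable.
    """

    def __init__(self, message: str, key: str = ""):
        super().__init__(message)
        self.key = key


class SingularParameterError(PoretransError):
    """A scaling relation is singular for the supplied exponents."""


class AnalysisError(PoretransError):
    """An estimator's preconditions are not met (empty input, bad domain)."""
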