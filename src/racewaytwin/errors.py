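"""Exception hierarchy for the raceway twin.

All errors raised on purpose by this package derive from :class:`RacewayError`
so callers can catch package failures without swallowing programming errors.
"""


class RacewayError(Exception):
    """Base class for all racewaytwin errors."""


class FormatError(RacewayError):
    """A file does not follow the expected CSV/config format."""


class DataGapError(RacewayError):
    """A forcing series has a gap too long to interpolate."""

    def __init__(self, message: str, gap_start=None, gap_end=None):
        super().__init__(message)
        self.gap_start = gap_start
        self.gap_end = gap_end


class DomainError(RacewayError):
    """A physical quantity is outside its valid domain."""


class ConfigurationError(RacewayError):
    """A configuration document violates the schema or its invariants."""


class CFLError(ConfigurationError):
    """Requested time step violates the advective stability bound."""

    def __init__(self, message: str, dt_max_h: float):
        super().__init__(message)
        self.dt_max_h = dt_max_h


class StarvationCollapse(RacewayError):
    """A growth trajectory drove fish weight to zero or below."""

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step
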