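"""Exception hierarchy shared across the pipeline."""


class PlumemixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlumemixError, ValueError):
    """A configuration field is invalid; the message names the field."""


class UnitError(PlumemixError, ValueError):
    """An unrecognized concentration unit."""


class InsufficientDataError(PlumemixError, ValueError):
    """Too few records for the requested statistic."""


class DegenerateInputError(PlumemixError, ValueError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class LookupError_(PlumemixError, KeyError):
    """A coordinate fell outside the bathymetry grid extent."""


class DataError(PlumemixError, ValueError):
    """A record violates a physical invariant (e.g. negative bottom depth)."""
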