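"""Exception hierarchy.

Everything derives from :class:`FishensError` so callers can catch the
package's failures in one clause; each subclass also derives from
``ValueError`` because every failure here is ultimately a bad input.
"""


class FishensError(Exception):
    """Base class for all errors raised by fishens."""


class ConfigurationError(FishensError, ValueError):
    """A configuration value (label, form name, grid spec, file) is invalid."""


class DomainError(FishensError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ForcingError(FishensError, ValueError):
    """A forcing series is missing, non-finite or non-positive."""


class RegimeError(FishensError, ValueError):
    """A fishing-mortality vector violates the regime's convention."""


class DataError(FishensError, ValueError):
    """Simulation output is incomplete or ragged for the requested analysis."""


class UndefinedIndexError(FishensError, ValueError):
    """An agreement statistic is undefined for the given inputs (e.g. N < 2)."""
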