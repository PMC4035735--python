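"""Exception hierarchy.

Errors are split by provenance: bad configuration (caller-supplied
parameters), bad data (images / tables), statistical degeneracy
(estimable-model violations), and misuse of the API contract.
"""


class AtrophyMapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AtrophyMapError):
    """A parameter value is invalid; the message names the field."""


class DataError(AtrophyMapError):
    """Input images or tables violate a precondition (grids, finiteness)."""


class StatisticsError(AtrophyMapError):
    """A model cannot be estimated (zero variance, no events, ...)."""


class CollinearityError(StatisticsError):
    """Design matrix is rank deficient; the message names the terms."""


class UsageError(AtrophyMapError):
    """API contract misuse (e.g. double normalization)."""
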