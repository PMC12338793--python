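"""Exception hierarchy for desertscan."""


class DesertscanError(Exception):
    """Base class for all desertscan errors."""


class ConfigError(DesertscanError):
    """Invalid generator or pipeline configuration; names the offending field."""


class DataError(DesertscanError):
    """Input data violates a documented invariant (bad proportions, bad GEOID, ...)."""


class DegenerateTractError(DataError):
    """Tract with zero total population: access fractions are undefined."""


class MissingDataError(DataError):
    """Required field absent (e.g. income); caller should exclude the tract."""
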