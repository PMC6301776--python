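"""Exception hierarchy for survey ingestion and estimation."""


class PenshellError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PenshellError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(PenshellError):
    """A record violates a domain invariant (negative length, bad area, ...)."""


class EmptyStratumError(PenshellError):
    """A stratification was requested for which no quadrats qualify."""


class ConfigError(PenshellError):
    """A scenario or run configuration file is malformed."""


class ExpansionError(PenshellError):
    """Counted-but-unmeasured individuals cannot be expanded without a
    measured size structure in the same quadrat."""
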