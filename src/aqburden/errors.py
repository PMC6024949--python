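"""Exception hierarchy for the assessment pipeline.

Every stage raises a subclass of :class:`AqBurdenError`, so callers can
fail fast on any pipeline problem with a single except clause while tests
can still pin down the specific failure mode.
"""


class AqBurdenError(Exception):
    """Base class for all package errors."""


class SchemaError(AqBurdenError):
    """An input table is missing a required column or has a bad header."""


class ValidationError(AqBurdenError):
    """A row or field violates a domain invariant (negative incidence, etc.)."""


class MissingDataError(AqBurdenError):
    """A required value (e.g. all monthly concentrations) is absent."""


class CalibrationError(AqBurdenError):
    """The synthetic-panel calibration targets are jointly infeasible."""


class PairingError(AqBurdenError):
    """Impact and cost records do not share the same (city, year, endpoint) key."""


class AggregationError(AqBurdenError):
    """A rollup found a gap (missing endpoint for a city-year)."""


class ConfigError(AqBurdenError):
    """Run or endpoint configuration is inconsistent or unknown."""


class DistributionError(AqBurdenError):
    """A Monte Carlo input distribution is mis-specified."""
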