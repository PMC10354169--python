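"""Exception hierarchy for the tracing pipeline.

All pipeline errors derive from :class:`CryotraceError` so callers can
catch the whole family; the subclasses distinguish bad isotope values,
physically impossible inputs, records with missing measurements, and
configuration mistakes.
"""


class CryotraceError(Exception):
    """Base class for all package errors."""


class InvalidIsotopeValueError(CryotraceError, ValueError):
    """An isotope value outside its physically valid range."""


class DomainError(CryotraceError, ValueError):
    """A non-isotope input outside its physically valid domain."""


class IncompleteObservationError(CryotraceError, ValueError):
    """A record is missing a measurement required by the computation."""


class QuantificationError(CryotraceError, ValueError):
    """Internal-standard quantification cannot proceed."""


class ConfigError(CryotraceError, ValueError):
    """An invalid configuration value."""
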