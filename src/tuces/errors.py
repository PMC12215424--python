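"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`TucesError`,
so callers can catch one type at a pipeline boundary while tests assert the
specific subclass.
"""


class TucesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TucesError):
    """A config object, parameter table or constant violates its contract."""


class DomainError(TucesError):
    """An input value is outside the mathematical domain of an operation."""


class DimensionError(TucesError):
    """Grids or vectors that must align do not."""


class MappingError(TucesError):
    """A reclassification table does not cover every code present."""


class EmptyDomainError(TucesError):
    """An aggregate was requested over an empty set (all nodata, no flows)."""


class DegenerateIndicatorError(TucesError):
    """An indicator is constant over its pooling window; min-max is undefined."""


class ZeroVarianceError(DomainError):
    """A statistic requiring variance was asked of a constant vector."""


class UndefinedCouplingError(DomainError):
    """Coupling degree is 0/0 when both subsystem values are zero."""


class AlignmentError(TucesError):
    """Two keyed tables that must share keys (cities, years) do not."""
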