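"""Exception hierarchy.

All package errors derive from :class:`NeighborGrowthError` so callers can
catch one base class; subclasses mirror the kinds of failure the pipeline
can produce (bad schema, broken referential integrity, invalid numeric
domain, geometry lookups).
"""


class NeighborGrowthError(Exception):
    """Base class for all package errors."""


class SchemaError(NeighborGrowthError):
    """A required logical column is missing from an input table."""


class IntegrityError(NeighborGrowthError):
    """Referential or uniqueness constraint violated (duplicate ids, unknown labels)."""


class DataError(NeighborGrowthError):
    """Input values are inconsistent (non-positive census interval, non-finite response)."""


class DomainError(NeighborGrowthError, ValueError):
    """A numeric argument is outside its valid domain (negative distance, dbh < 0)."""


class JoinError(NeighborGrowthError):
    """Species codes present in the growth table are missing from the species table."""


class AssignmentError(NeighborGrowthError):
    """A point could not be assigned to any fold block."""


class FoldLookupError(NeighborGrowthError, KeyError):
    """A fold id is not present in the partition."""


class ShapeError(NeighborGrowthError, ValueError):
    """Array dimensions do not conform."""


class ValidationError(NeighborGrowthError):
    """A model hyperparameter object violates its invariants (non-SPD precision, a0 <= 0)."""
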