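"""Exception hierarchy for nichespace."""


class NicheSpaceError(Exception):
    """Base class for all nichespace errors."""


class ValidationError(NicheSpaceError, ValueError):
    """Invalid argument or configuration value."""


class ParseError(ValidationError):
    """A cell in an input table could not be parsed; names row and column."""


class DuplicateTaxonError(ValidationError):
    """A taxon identifier appears more than once."""


class MissingValueError(ValidationError):
    """A required cell is empty; names the offending cell."""


class EmptyTaxonError(ValidationError):
    """A taxon has no individual records."""


class DimensionError(ValidationError):
    """Vector or matrix dimensions do not agree."""


class AxisNotFoundError(NicheSpaceError, KeyError):
    """A named axis does not exist in the community."""


class InsufficientTaxaError(ValidationError):
    """Too few taxa for the requested computation."""


class DegenerateGeometryError(NicheSpaceError):
    """Points lie in a lower-dimensional affine subspace; hull volume undefined."""


class UndefinedCIError(NicheSpaceError):
    """A confidence interval could not be formed (no defined replicates)."""
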