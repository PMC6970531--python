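"""Exception hierarchy shared across the package."""


class RnapconfError(Exception):
    """Base class for all package errors."""


class StructureParseError(RnapconfError):
    """Coordinate file could not be parsed."""


class EmptyModelError(RnapconfError):
    """A coordinate model contains no atoms."""


class SelectionSyntaxError(RnapconfError):
    """Selection expression does not match the grammar."""


class SelectionRangeError(RnapconfError):
    """Residue range with start > end."""


class SelectionError(RnapconfError):
    """A selection was empty where atoms were required."""


class ConfigurationError(RnapconfError):
    """Missing or inconsistent configuration (e.g. chain map)."""


class InsufficientAtomsError(RnapconfError):
    """Too few paired atoms for the requested geometric operation."""


class NotARotationError(RnapconfError):
    """Matrix fails the orthonormal / det(+1) validation."""


class DegenerateSeriesError(RnapconfError):
    """Eigenvalue series has zero variance or too few values."""


class EigenTableError(RnapconfError):
    """Eigenvalue table could not be parsed or lacks the column."""


class LandscapeError(RnapconfError):
    """Energy landscape violates its invariants (barrier below a well, ...)."""


class ConvergenceError(RnapconfError):
    """Iterative solver failed to reach the requested residual."""
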