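"""Exception hierarchy for metallobuild.

All package-specific failures derive from :class:`MetallobuildError` so
callers can catch one base class at pipeline boundaries.
"""


class MetallobuildError(Exception):
    """Base class for all metallobuild errors."""


class UnsupportedElementError(MetallobuildError):
    """Element symbol is unknown or outside the supported table."""


class InconsistentStateError(MetallobuildError):
    """An electronic-state override violates electron-count parity."""


class UnsupportedCNError(MetallobuildError):
    """Coordination number outside the supported 1-12 range."""


class UnsupportedDenticityError(MetallobuildError):
    """No ligand type is defined for the requested denticity."""


class DegenerateInputError(MetallobuildError):
    """Geometric input is degenerate (zero vector, coincident sites...)."""


class ImpossiblePlacementError(MetallobuildError):
    """Ligand denticity exceeds the core coordination number."""


class LigandParseError(MetallobuildError):
    """SMILES could not be parsed or CA indices are out of range."""


class DisconnectedGraphError(MetallobuildError):
    """Ligand molecular graph is not connected."""


class EmbeddingError(MetallobuildError):
    """Distance-geometry embedding failed to satisfy its bounds.

    Carries ``worst_pair`` (i, j) and ``violation`` (Å) when available.
    """

    def __init__(self, message, worst_pair=None, violation=None):
        super().__init__(message)
        self.worst_pair = worst_pair
        self.violation = violation


class CleaningError(MetallobuildError):
    """Force-field cleanup failed or left a broken bond."""


class AssemblyInfeasibleError(MetallobuildError):
    """Every candidate conformer for some ligand failed placement checks."""

    def __init__(self, message, ligand_index=None):
        super().__init__(message)
        self.ligand_index = ligand_index


class RelaxationError(MetallobuildError):
    """The calculator failed during geometry relaxation."""


class IncomparableStructuresError(MetallobuildError):
    """Structures do not share an element multiset."""


class BuildFailedError(MetallobuildError):
    """No conformer survived the build pipeline.

    ``report`` holds the per-stage attrition accounting.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
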