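"""Exception hierarchy shared across the analysis modules."""


class MolprofError(Exception):
    """Base class for all molprof errors."""


class InvalidInputError(MolprofError, ValueError):
    """Non-finite, non-positive or otherwise out-of-domain input."""


class DegenerateHardnessError(MolprofError, ZeroDivisionError):
    """I == A within tolerance: hardness vanishes and softness and the
    electrophilicity family are undefined."""


class MissingFragmentError(MolprofError, KeyError):
    """A group-count profile references a symbol absent from the library."""


class UnderDeterminedError(MolprofError, ValueError):
    """Fewer independent reference equations than unknown contributions."""


class OverDeterminedUnknownsError(MolprofError, ValueError):
    """A single-compound derivation found more than one unknown symbol."""


class SingularSystemError(MolprofError, ValueError):
    """Rank-deficient design matrix in a contribution fit."""


class IncompleteDecompositionError(MolprofError, ValueError):
    """Substructure assignment left heavy atoms uncovered.

    Carries the partial profile and the uncovered atom indices so callers
    can inspect what failed instead of receiving a silently truncated count.
    """

    def __init__(self, message, profile=None, unassigned=None):
        super().__init__(message)
        self.profile = profile
        self.unassigned = tuple(unassigned or ())


class DecompositionParseError(MolprofError, ValueError):
    """SMILES string could not be parsed."""


class MissingDataError(MolprofError, KeyError):
    """Required gene/group combination absent from a Ct table."""


class InvalidDesignError(MolprofError, ValueError):
    """Statistically meaningless request, e.g. reference gene == target."""


class DegenerateVarianceError(MolprofError, ValueError):
    """Zero pooled variance with unequal means, or too few replicates."""


class SchemaError(MolprofError, ValueError):
    """Malformed input file: missing columns, duplicates, bad values."""


class GenerationError(MolprofError, RuntimeError):
    """Synthetic-data generator could not satisfy its post-conditions."""


class NonAufbauWarning(UserWarning):
    """Emitted when E(HOMO) > E(LUMO), i.e. a non-Aufbau orbital ordering."""
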