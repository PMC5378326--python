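"""Exception hierarchy for the deltol package."""


class DeltolError(Exception):
    """Base class for all deltol errors."""


class EmptyStructureError(DeltolError):
    """No ATOM records survived parsing / chain filtering."""


class PDBParseError(DeltolError):
    """A PDB record could not be parsed; the message names the line."""


class MissingAtomError(DeltolError):
    """A residue lacks the atoms needed for the requested computation."""


class SingularDistanceError(DeltolError):
    """Two side-chain centers coincide, making 1/r**2 undefined."""


class RadiusLookupError(DeltolError):
    """No van der Waals radius is known for an element."""


class MaxASALookupError(DeltolError):
    """Residue name absent from the maximum-ASA normalization table."""


class JoinError(DeltolError):
    """A mutant position could not be matched to exactly one residue."""


class SchemaError(DeltolError):
    """A delimited table is missing required columns or rows."""


class EncodingError(DeltolError):
    """A feature table has missing values in columns needed by a model."""


class DegenerateLabelError(DeltolError):
    """Only one functional class present where both are required."""


class UndefinedAUCError(DegenerateLabelError):
    """ROC/AUC undefined because one class is absent."""


class DegenerateTableError(DeltolError):
    """A contingency table has a zero marginal."""


class PackingError(DeltolError):
    """A random point cloud could not satisfy the separation constraint."""
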