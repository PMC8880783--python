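"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`CofnetError`
so callers (and the CLI) can separate analysis failures from programming bugs.
"""


class CofnetError(Exception):
    """Base class for all cofnet errors."""


class StructureParseError(CofnetError):
    """A coordinate file could not be parsed under the requested dialect."""


class FormatError(CofnetError):
    """Unknown or unsupported file format."""


class FormatCapacityError(FormatError):
    """An identifier does not fit the fixed columns of legacy PDB; use mmCIF."""


class SelectionSyntaxError(CofnetError):
    """Selection expression failed to parse; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class AmbiguousComponentError(CofnetError):
    """A residue name matched more than one cofactor type in the dictionary."""


class DegenerateCofactorError(CofnetError):
    """A cofactor with no usable atoms was passed to a distance computation."""


class LabelError(CofnetError):
    """Duplicate or missing cofactor labels."""


class PairingError(CofnetError):
    """Atom pairing between two structures failed (count/identity mismatch)."""


class DegenerateGeometryError(CofnetError):
    """Superposition input is rank-deficient (collinear or coincident points)."""


class InfeasibleConstraintsError(CofnetError):
    """The placement solver could not satisfy the distance constraints."""

    def __init__(self, message: str, violations=None):
        super().__init__(message)
        self.violations = violations or []
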