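"""Exception hierarchy for bizinc.

All package-specific failures derive from :class:`BizincError` so callers can
catch one base class at pipeline boundaries.
"""


class BizincError(Exception):
    """Base class for all bizinc errors."""


class ParseError(BizincError):
    """A structure file could not be parsed."""


class FormatError(BizincError):
    """An unknown or unsupported file format was requested."""


class SerializationError(BizincError):
    """Output could not be serialized (e.g. non-finite grid values)."""


class EmptyComponentError(BizincError):
    """A residue/ligand component holds no atoms."""


class GenerationError(BizincError):
    """A synthetic site specification is geometrically infeasible."""


class ParameterError(BizincError):
    """An invalid parameter value was supplied."""


class SelectionError(BizincError):
    """An atom/residue selection matched nothing or was ambiguous."""


class DegenerateGeometryError(BizincError):
    """A superposition pairing is collinear or otherwise degenerate."""


class FrameError(BizincError):
    """A headgroup frame is malformed (wrong number of base atoms...)."""


class PairingError(BizincError):
    """Atoms/metals of two structures could not be matched."""


class RecipeError(BizincError):
    """A cluster recipe references residues absent from the structure."""


class UnitError(BizincError):
    """Energies with incompatible units were combined."""


class TableError(BizincError):
    """An energy table is empty or inconsistent."""


class DomainError(BizincError):
    """A mathematical operation was evaluated outside its domain."""
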