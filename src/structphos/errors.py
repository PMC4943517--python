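"""Exception hierarchy."""


class StructphosError(Exception):
    """Base class for all package errors."""


class ParseError(StructphosError):
    """A structure document could not be parsed; carries context (line)."""


class EmptyStructureError(StructphosError):
    """Parsing yielded zero residues."""


class MissingGeometryError(StructphosError):
    """A residue lacks the atoms needed for a geometric primitive."""


class DegenerateGeometryError(StructphosError):
    """Point set unsuitable for tessellation (coplanar / too few points)."""


class SchemaError(StructphosError):
    """An external feature table is missing required columns."""


class DegenerateLabelError(StructphosError):
    """A labelled operation received a single-class target vector."""
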