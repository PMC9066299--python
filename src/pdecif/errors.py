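"""Exception types shared across the package."""


class PdecifError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(PdecifError, ValueError):
    """A PDB/MOL/SDF/index file could not be parsed."""


class EmptyStructureError(PdecifError, ValueError):
    """A structure contains no usable (heavy, typeable) atoms."""


class EmptyComplexError(PdecifError, ValueError):
    """Neither side of a complex has a typeable heavy atom."""


class DegenerateMatrixError(PdecifError, ValueError):
    """A feature matrix is unusable (e.g. every column is zero)."""


class VocabularyError(PdecifError, ValueError):
    """An atom-type vocabulary failed its internal consistency check."""


class GenerationError(PdecifError, ValueError):
    """A synthetic fixture could not be generated (e.g. clashing atoms)."""
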