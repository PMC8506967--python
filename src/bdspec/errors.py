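"""Exception hierarchy shared across the pipeline."""


class BdspecError(Exception):
    """Base class for all package errors."""


class ParseError(BdspecError):
    """A structure or alignment file could not be parsed."""


class SelectionError(BdspecError):
    """A chain/residue selection does not match the structure."""


class GeometryError(BdspecError):
    """Degenerate geometry: undefined dihedral, rank-deficient superposition."""


class SuperpositionError(GeometryError):
    """Rigid-body fit failed or the pruned pair set collapsed."""


class AlignmentFormatError(ParseError):
    """Ragged rows, duplicate ids, or a missing reference row in an MSA."""


class GenerationError(BdspecError):
    """A synthetic-data spec could not be realized."""


class ConfigError(BdspecError):
    """Pipeline configuration is invalid or incomplete."""


class StageError(BdspecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
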