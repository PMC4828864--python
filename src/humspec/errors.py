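"""Named exceptions shared across the package."""


class HumspecError(Exception):
    """Base class for all package errors."""


class PanelError(HumspecError):
    """Malformed ortholog panel (unequal lengths, bad alphabet, empty)."""


class PlantingError(HumspecError):
    """Invalid planted-substitution specification."""


class CdsError(HumspecError):
    """CDS not translatable (length not a multiple of three, bad alphabet)."""


class UnknownClassError(HumspecError):
    """Variant consequence class outside the fixed vocabulary."""


class DuplicateIdError(HumspecError):
    """Duplicate protein id where ids must be unique."""


class UnknownIdError(HumspecError):
    """Referenced protein id absent from the annotation pool."""


class DegenerateMatrixError(HumspecError):
    """Score matrix with constant off-diagonal (weight range undefined)."""


class MissingPairError(HumspecError):
    """Residue pair absent from a weight table."""


class IdMismatchError(HumspecError):
    """Two collections expected over the same id set differ."""


class EmptyInputError(HumspecError):
    """Operation requires at least one element."""


class PlacementError(HumspecError):
    """Synthetic clusters could not be placed without overlap."""


class ZeroReferenceError(HumspecError):
    """Normalization reference with no clusters of at least 10 cells."""


class InsufficientReplicatesError(HumspecError):
    """Statistical test requires more conditions or replicates."""


class ConfigError(HumspecError):
    """Invalid pipeline run configuration."""


class StageError(HumspecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
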