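"""Exception hierarchy for the papillae pipeline."""


class PapillaeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PapillaeError):
    """Unsupported or malformed file format."""


class PointParseError(FormatError):
    """Malformed annotation record; message names the offending line."""


class ValidationError(PapillaeError, ValueError):
    """Input violates a documented precondition or invariant."""


class DetectionError(PapillaeError):
    """Stain-region detection found no usable component."""


class PlacementError(PapillaeError):
    """Synthetic spot placement could not satisfy the separation constraint."""


class StageError(PapillaeError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class TrainingDivergedError(PapillaeError):
    """Loss became non-finite; message names the epoch."""
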