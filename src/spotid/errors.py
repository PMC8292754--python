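"""Exception types shared across the pipeline."""


class SpotIDError(Exception):
    """Base class for all package-specific errors."""


class NoSubjectFoundError(SpotIDError):
    """No foreground component was found when extracting a body mask."""


class EmptyMaskError(SpotIDError):
    """An operation that requires a non-empty mask received an empty one."""


class DegenerateMaskError(SpotIDError):
    """Mask has too little spatial extent for PCA alignment."""


class TooFewSpotsError(SpotIDError):
    """Fewer than three spots; no triangles can be built."""


class DegenerateConfigurationError(SpotIDError):
    """Collinear or coincident points; transform estimation is ill-posed."""


class ChronologyViolationError(SpotIDError):
    """A collection was inserted out of chronological order."""


class ConflictError(SpotIDError):
    """A match decision links two records from the same collection."""


class ParseError(SpotIDError):
    """A file could not be parsed; carries the offending line if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(SpotIDError):
    """Parsed data violates a container invariant."""
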