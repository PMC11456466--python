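"""Exception hierarchy shared by all cabbagepose modules."""


class CabbageError(Exception):
    """Base class for all cabbagepose errors."""


class EmptyMaskError(CabbageError):
    """An operation requiring at least one foreground pixel received an empty mask."""

    def __init__(self, message: str = "empty instance"):
        super().__init__(message)


class SchemaError(CabbageError):
    """An annotation file is structurally invalid (missing/ambiguous labels, bad fields)."""


class GeometryError(CabbageError):
    """Geometric parameters place an object (partly) outside the usable frame."""


class NoIntersectionError(CabbageError):
    """The sampled growth curve never enters the head mask.

    Usually cured by a denser sampling grid (larger ``n_samples``) or by
    checking that the head mask is a filled region.
    """


class ConfigError(CabbageError):
    """Invalid run configuration (unknown keys, out-of-range values)."""


class StageError(CabbageError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage={stage}: {cause}")
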