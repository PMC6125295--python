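"""Exception hierarchy.

``FdgPatternError`` is the base for everything the library raises on bad
input; the CLI maps it to exit code 3 (data error).
"""


class FdgPatternError(Exception):
    """Base class for all library errors."""


class MissingFileError(FdgPatternError):
    """Input path does not exist."""


class NotNiftiError(FdgPatternError):
    """File exists but is not a readable NIfTI-1/NIfTI-2 payload."""


class NonFiniteDataError(FdgPatternError):
    """Volume or matrix contains NaN or infinite values."""


class DimensionError(FdgPatternError):
    """Volume has more than 3 non-singleton dimensions."""


class ShapeMismatchError(FdgPatternError):
    """Grids of volumes/masks/patterns do not agree."""


class EmptyMaskError(FdgPatternError):
    """Analysis mask selects zero voxels."""


class DegenerateScanError(FdgPatternError):
    """A scan with non-positive in-mask mean cannot be proportionally scaled."""


class LabelError(FdgPatternError):
    """Group labels are missing, not two-group, or misaligned with volumes."""


class MaskMismatchError(FdgPatternError):
    """Model and data were built on different masks / voxel orders."""


class ModelStateError(FdgPatternError):
    """Model is not in the state an operation requires (e.g. no threshold)."""


class NonPositiveValueError(FdgPatternError):
    """Log-transform step received a voxel value <= 0."""


class ConfigError(FdgPatternError):
    """Invalid run configuration or cohort specification."""
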