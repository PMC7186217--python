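"""Typed errors shared across the pipeline stages.

Every stage raises a subclass of :class:`VoxelFcError` so callers can
distinguish data problems from configuration problems.
"""


class VoxelFcError(Exception):
    """Base class for all voxelfc errors."""


class SpatialFrameError(VoxelFcError):
    """Volumes, masks or atlases do not share a spatial frame."""


class DegenerateInputError(VoxelFcError):
    """Input too small or empty to be meaningful (e.g. <2 timepoints)."""


class DataQualityError(VoxelFcError):
    """Non-finite or otherwise unusable values inside the brain mask."""


class DegenerateMaskError(VoxelFcError):
    """Mask construction produced an empty mask."""


class ParameterError(VoxelFcError):
    """A numeric parameter is outside its valid range."""


class NumericalError(VoxelFcError):
    """A numeric routine produced non-finite intermediate values."""


class DegenerateComponentError(VoxelFcError):
    """A spatial map has zero variance and cannot be z-scored."""


class SelectionError(VoxelFcError):
    """Component stability selection is infeasible."""


class PipelineDegenerateError(VoxelFcError):
    """A stage produced an output on which the pipeline cannot continue
    (e.g. fewer than two joint common activity voxels)."""


class DegenerateVoxelError(VoxelFcError):
    """A voxel time series has zero variance where a correlation is needed."""


class GroupingError(VoxelFcError):
    """Subjects passed to a group-level operation have inconsistent labels."""


class SampleSizeError(VoxelFcError):
    """Too few subjects per group for a two-sample test."""


class AlignmentError(VoxelFcError):
    """Paired feature sets do not refer to the same subjects."""


class ConfigurationError(VoxelFcError):
    """Invalid pipeline or protocol configuration."""


class FeasibilityError(VoxelFcError):
    """A requested synthetic effect cannot be generated."""


class FormatError(VoxelFcError):
    """A file does not conform to the expected format."""


class IcaConvergenceWarning(UserWarning):
    """Fixed-point ICA hit the iteration cap; the best estimate is returned."""
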