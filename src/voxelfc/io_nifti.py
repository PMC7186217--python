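"""NIfTI input/output, brain-mask construction and the canonical voxel order.

Every downstream stage works on in-mask time×voxel matrices.  The canonical
linearization of a 3-D grid orders voxel (x, y, z) with x fastest and z
slowest (Fortran order, 0-based); all voxel indices elsewhere in the package
are *positions within the in-mask ordering* induced by this rule, so column
``j`` of every subject matrix refers to the same spatial location.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DataQualityError,
    DegenerateInputError,
    DegenerateMaskError,
    FormatError,
    ParameterError,
    SpatialFrameError,
)

__all__ = [
    "VolumeGrid",
    "BrainMask",
    "SubjectMatrix",
    "AtlasLabels",
    "load_subject_volume",
    "save_subject_volume",
    "build_group_mask",
    "load_atlas",
    "bandpass_detrend",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Spatial frame: grid shape plus voxel→world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4), compare=False
    )

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ParameterError(f"grid shape must be 3 positive ints, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or not np.isfinite(np.linalg.det(affine)) or np.linalg.det(affine) == 0:
            raise ParameterError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", affine)

    @property
    def n_grid_voxels(self) -> int:
        return int(np.prod(self.shape))

    def same_frame(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (homo @ self.affine.T)[:, :3]


class BrainMask:
    """Set of in-brain voxels on a grid, with the canonical in-mask ordering.

    Parameters
    ----------
    grid : VolumeGrid
    flags : ndarray of bool, shape ``grid.shape``
        True where the voxel is inside the brain mask.
    """

    def __init__(self, grid: VolumeGrid, flags: np.ndarray):
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != grid.shape:
            raise SpatialFrameError(
                f"mask flags shape {flags.shape} != grid shape {grid.shape}"
            )
        self.grid = grid
        self.flags = flags
        # canonical order: x fastest, z slowest == Fortran raveling
        self.flat_indices = np.flatnonzero(flags.ravel(order="F"))
        self.n_voxels = int(self.flat_indices.size)
        if self.n_voxels < 2:
            raise DegenerateMaskError(
                f"mask must contain at least 2 voxels, got {self.n_voxels}"
            )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BrainMask)
            and self.grid.same_frame(other.grid)
            and np.array_equal(self.flags, other.flags)
        )

    def __hash__(self) -> int:  # identity hash; equality is structural
        return id(self)

    def voxel_coordinates(self, inmask_positions: np.ndarray | None = None) -> np.ndarray:
        """(n, 3) integer grid coordinates of in-mask voxels (canonical order)."""
        flat = self.flat_indices
        if inmask_positions is not None:
            flat = flat[np.asarray(inmask_positions, dtype=int)]
        nx, ny, _ = self.grid.shape
        x = flat % nx
        y = (flat // nx) % ny
        z = flat // (nx * ny)
        return np.stack([x, y, z], axis=1)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-``n_voxels`` vector back onto the 3-D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise SpatialFrameError("vector length does not match mask size")
        flat = np.full(self.grid.n_grid_voxels, fill, dtype=values.dtype)
        flat[self.flat_indices] = values
        return flat.reshape(self.grid.shape, order="F")


@dataclass
class SubjectMatrix:
    """One subject's in-mask data: rows are timepoints, columns are voxels
    in the canonical in-mask order."""

    subject_id: str
    group_label: str
    data: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DegenerateInputError("subject data must be a 2-D time x voxel matrix")
        if self.data.shape[0] < 2:
            raise DegenerateInputError(
                f"subject {self.subject_id!r} has {self.data.shape[0]} timepoints; need >=2"
            )
        if self.data.shape[1] != self.mask.n_voxels:
            raise SpatialFrameError(
                f"subject {self.subject_id!r}: {self.data.shape[1]} columns "
                f"!= {self.mask.n_voxels} mask voxels"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.unique(np.nonzero(~np.isfinite(self.data))[1])
            raise DataQualityError(
                f"subject {self.subject_id!r}: non-finite values at in-mask "
                f"voxel indices {bad[:20].tolist()}"
            )

    @property
    def t_points(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[1])

    def validate_variance(self) -> None:
        """Raise if any in-mask voxel has zero temporal variance."""
        var = self.data.var(axis=0)
        if np.any(var <= 0):
            bad = np.flatnonzero(var <= 0)
            raise DataQualityError(
                f"subject {self.subject_id!r}: zero temporal variance at "
                f"in-mask voxel indices {bad[:20].tolist()}"
            )


@dataclass
class AtlasLabels:
    """Integer-labelled parcellation aligned to a brain mask (0 = unlabeled)."""

    grid: VolumeGrid
    labels: np.ndarray  # 3-D int array on the grid
    region_names: dict[int, str]
    region_sizes: dict[int, int]  # in-mask voxel count per nonzero label
    mask: BrainMask

    @property
    def inmask_labels(self) -> np.ndarray:
        """Label of each in-mask voxel, canonical order."""
        return self.labels.ravel(order="F")[self.mask.flat_indices]


def _drop_trailing_singleton(data: np.ndarray) -> np.ndarray:
    # 3-D volumes are sometimes stored with a trailing length-1 time axis
    if data.ndim == 4 and data.shape[3] == 1:
        return data[..., 0]
    return data


def _as_4d_array(volume) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a path, a nibabel image or an ndarray; return (data, affine)."""
    if isinstance(volume, (str, Path)):
        img = nib.load(str(volume))
        return np.asarray(img.dataobj, dtype=float), img.affine
    if isinstance(volume, nib.spatialimages.SpatialImage):
        return np.asarray(volume.dataobj, dtype=float), volume.affine
    return np.asarray(volume, dtype=float), None


def load_subject_volume(
    path,
    mask: BrainMask,
    group_label: str,
    subject_id: str | None = None,
) -> SubjectMatrix:
    """Extract a subject's T×V in-mask matrix from a 4-D volume.

    Timepoints are preserved in acquisition order; columns follow the mask's
    canonical voxel ordering.
    """
    data, _ = _as_4d_array(path)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D volume, got ndim={data.ndim}")
    if data.shape[:3] != mask.grid.shape:
        raise SpatialFrameError(
            f"volume spatial shape {data.shape[:3]} != mask grid {mask.grid.shape}"
        )
    t_points = data.shape[3]
    if t_points < 2:
        raise DegenerateInputError(f"volume has {t_points} timepoints; need >=2")
    flat = data.reshape(-1, t_points, order="F")  # (grid voxels, T)
    matrix = flat[mask.flat_indices].T  # T x V
    if subject_id is None:
        subject_id = Path(str(path)).name if isinstance(path, (str, Path)) else "subject"
    return SubjectMatrix(subject_id=subject_id, group_label=group_label,
                         data=matrix, mask=mask)


def save_subject_volume(subject: SubjectMatrix, path) -> None:
    """Write a subject matrix back into its grid as a 4-D NIfTI (zeros
    outside the mask).  Stored as float64 so reloading is bitwise exact."""
    grid = subject.mask.grid
    t = subject.t_points
    flat = np.zeros((grid.n_grid_voxels, t))
    flat[subject.mask.flat_indices] = subject.data.T
    vol = flat.reshape(grid.shape + (t,), order="F")
    img = nib.Nifti1Image(vol, grid.affine)
    img.set_data_dtype(np.float64)
    nib.save(img, str(path))


def build_group_mask(volumes: list, explicit_mask=None) -> BrainMask:
    """Build the analysis mask automatically from the data itself.

    A voxel is kept iff its time series has strictly positive variance in
    every listed volume (so Pearson correlations are defined everywhere
    in-mask); an explicit mask, when given, is intersected with that set.
    """
    if not volumes:
        raise DegenerateInputError("need at least one volume to build a mask")
    keep = None
    affine = None
    shape = None
    for vol in volumes:
        data, aff = _as_4d_array(vol)
        if data.ndim != 4:
            raise FormatError("mask construction expects 4-D volumes")
        if shape is None:
            shape = data.shape[:3]
            affine = aff if aff is not None else np.eye(4)
        elif data.shape[:3] != shape:
            raise SpatialFrameError(
                f"volume shape {data.shape[:3]} != first volume shape {shape}"
            )
        positive = data.var(axis=3) > 0
        keep = positive if keep is None else (keep & positive)
    if explicit_mask is not None:
        mdata, maff = _as_4d_array(explicit_mask)
        mdata = _drop_trailing_singleton(mdata)
        if mdata.shape != shape:
            raise SpatialFrameError(
                f"explicit mask shape {mdata.shape} != volume shape {shape}"
            )
        keep = keep & (mdata != 0)
        if maff is not None:
            affine = maff
    if not keep.any():
        raise DegenerateMaskError("group mask is empty")
    grid = VolumeGrid(shape=shape, affine=affine)
    return BrainMask(grid, keep)


def load_atlas(path, mask: BrainMask, names=None) -> AtlasLabels:
    """Load an integer-labelled atlas volume aligned to the mask.

    ``names`` may be a {label: name} mapping or a two-column TSV path
    (label, name); missing labels are auto-named ``region_<label>``.
    """
    data, _ = _as_4d_array(path)
    data = _drop_trailing_singleton(data)
    if data.ndim != 3:
        raise FormatError("atlas must be a 3-D volume")
    if data.shape != mask.grid.shape:
        raise SpatialFrameError(
            f"atlas shape {data.shape} != mask grid {mask.grid.shape}"
        )
    rounded = np.round(data)
    if not np.allclose(data, rounded) or np.any(rounded < 0):
        raise FormatError("atlas labels must be nonnegative integers")
    labels = rounded.astype(int)

    name_map: dict[int, str] = {}
    if isinstance(names, (str, Path)):
        table = pd.read_csv(names, sep="\t", header=None, names=["label", "name"])
        name_map = {int(r.label): str(r.name) for r in table.itertuples()}
    elif names:
        name_map = {int(k): str(v) for k, v in names.items()}

    inmask = labels.ravel(order="F")[mask.flat_indices]
    uniq, counts = np.unique(inmask[inmask > 0], return_counts=True)
    region_sizes = {int(k): int(c) for k, c in zip(uniq, counts)}
    region_names = {
        int(k): name_map.get(int(k), f"region_{int(k)}") for k in uniq
    }
    return AtlasLabels(grid=mask.grid, labels=labels, region_names=region_names,
                       region_sizes=region_sizes, mask=mask)


def bandpass_detrend(
    subject: SubjectMatrix,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_seconds: float = 3.0,
) -> SubjectMatrix:
    """Per-voxel linear detrend followed by a zero-phase Butterworth
    band-pass.  Optional stage: inputs are normally assumed preprocessed."""
    nyquist = 0.5 / tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ParameterError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    detrended = signal.detrend(subject.data, axis=0, type="linear")
    fs = 1.0 / tr_seconds
    if low_hz > 0:
        b, a = signal.butter(4, [low_hz, high_hz], btype="band", fs=fs)
    else:
        b, a = signal.butter(4, high_hz, btype="low", fs=fs)
    padlen = min(3 * (max(len(a), len(b)) - 1), subject.t_points - 1)
    filtered = signal.filtfilt(b, a, detrended, axis=0, padlen=padlen)
    return dataclasses.replace(subject, data=filtered)
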