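"""Activity-voxel sets: per-subject detection, group intersection, and
atlas-region summaries.

A voxel is *active* for a subject if any of its z-scored independent spatial
maps exceeds the threshold θ in absolute value; a group's common activity
voxels are the intersection of its subjects' sets, and the joint set of two
groups is the intersection of the two group sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

from .decompose import ZMaps
from .errors import ParameterError, PipelineDegenerateError, SpatialFrameError
from .io_nifti import AtlasLabels, BrainMask

__all__ = [
    "VoxelSet",
    "subject_active_voxels",
    "group_common_voxels",
    "joint_common_voxels",
    "summarize_regions",
]


@dataclass
class VoxelSet:
    """Ordered set of in-mask voxel indices (positions in the canonical
    in-mask ordering, not raw grid offsets)."""

    indices: np.ndarray
    mask: BrainMask
    provenance: str  # subject_avl | group_cavl | joint_cavl12

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).ravel()
        idx = np.unique(idx)  # sorted, strictly increasing
        if idx.size and (idx[0] < 0 or idx[-1] >= self.mask.n_voxels):
            raise SpatialFrameError("voxel index outside the in-mask range")
        self.indices = idx

    @property
    def n(self) -> int:
        return int(self.indices.size)

    def to_flags(self) -> np.ndarray:
        flags = np.zeros(self.mask.n_voxels, dtype=bool)
        flags[self.indices] = True
        return flags


def subject_active_voxels(zmaps: ZMaps, theta: float, mask: BrainMask) -> VoxelSet:
    """Voxels with |z| ≥ θ in at least one component (union over components).

    The comparison is inclusive. An empty result is permitted but warned
    about, since it empties every downstream intersection.
    """
    if theta <= 0:
        raise ParameterError(f"theta must be positive, got {theta}")
    active = np.flatnonzero(np.any(np.abs(zmaps.z) >= theta, axis=0))
    if active.size == 0:
        warnings.warn(
            f"subject {zmaps.subject_id!r}: no active voxels at theta={theta}",
            stacklevel=2,
        )
    return VoxelSet(indices=active, mask=mask, provenance="subject_avl")


def _check_same_mask(sets: list[VoxelSet]) -> BrainMask:
    mask = sets[0].mask
    for s in sets[1:]:
        if s.mask is not mask and s.mask != mask:
            raise SpatialFrameError("voxel sets do not share a brain mask")
    return mask


def group_common_voxels(avls: list[VoxelSet]) -> VoxelSet:
    """Intersection of per-subject activity sets over one cohort."""
    if not avls:
        raise ParameterError("need at least one subject activity set")
    mask = _check_same_mask(avls)
    common = reduce(np.intersect1d, (s.indices for s in avls))
    if common.size == 0:
        warnings.warn(
            "common activity set is empty; consider lowering theta", stacklevel=2
        )
    return VoxelSet(indices=common, mask=mask, provenance="group_cavl")


def joint_common_voxels(cavl1: VoxelSet, cavl2: VoxelSet) -> VoxelSet:
    """Common activity voxels of the two cohorts (the FC feature support)."""
    for s in (cavl1, cavl2):
        if s.provenance != "group_cavl":
            raise ParameterError(
                f"expected group_cavl provenance, got {s.provenance!r}"
            )
    mask = _check_same_mask([cavl1, cavl2])
    joint = np.intersect1d(cavl1.indices, cavl2.indices)
    if joint.size < 2:
        raise PipelineDegenerateError(
            f"only {joint.size} joint common activity voxel(s); no functional "
            "connectivity can be computed — consider lowering theta"
        )
    return VoxelSet(indices=joint, mask=mask, provenance="joint_cavl12")


def summarize_regions(
    voxels: VoxelSet,
    atlas: AtlasLabels,
    min_count: int = 10,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-region counts of active voxels, keeping regions with strictly
    more than ``min_count`` active voxels AND an active fraction strictly
    above ``min_fraction``; the representative coordinate is the world-mm
    centroid of the region's active voxels."""
    if not atlas.grid.same_frame(voxels.mask.grid):
        raise SpatialFrameError("atlas and voxel set are on different grids")
    labels = atlas.inmask_labels
    rows = []
    active_labels = labels[voxels.indices]
    for label in sorted(atlas.region_sizes):
        in_region = voxels.indices[active_labels == label]
        count = int(in_region.size)
        size = atlas.region_sizes[label]
        fraction = count / size
        if count > min_count and fraction > min_fraction:
            coords = voxels.mask.voxel_coordinates(in_region)
            centroid = atlas.grid.voxel_to_world(coords).mean(axis=0)
            rows.append(
                {
                    "label": label,
                    "region": atlas.region_names[label],
                    "voxel_number": count,
                    "voxel_ratio": fraction,
                    "x_mm": centroid[0],
                    "y_mm": centroid[1],
                    "z_mm": centroid[2],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["label", "region", "voxel_number", "voxel_ratio",
                 "x_mm", "y_mm", "z_mm"],
    )
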