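"""Per-subject functional-connectivity feature vectors.

An FC feature is the Pearson correlation between the raw time series of two
joint common activity voxels; the feature vector enumerates all unordered
pairs (p, q), p < q, of positions within the sorted joint set, in fixed
lexicographic order, so edge k refers to the same voxel pair in every
subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import VoxelSet
from .errors import (
    DegenerateInputError,
    DegenerateVoxelError,
    GroupingError,
    ParameterError,
)
from .io_nifti import SubjectMatrix

__all__ = ["EdgeIndex", "FcVector", "GroupFcMatrix", "fc_vector", "stack_group_fc"]


@dataclass
class EdgeIndex:
    """Fixed enumeration of voxel pairs: lexicographic by (p, q), p < q,
    over positions in the sorted joint common activity set."""

    voxel_indices: np.ndarray  # sorted in-mask voxel indices (the joint set)
    pairs: np.ndarray  # (edge_count, 2) positions into voxel_indices

    @classmethod
    def from_voxel_set(cls, cavl12: VoxelSet) -> "EdgeIndex":
        n = cavl12.n
        p, q = np.triu_indices(n, k=1)
        return cls(voxel_indices=cavl12.indices.copy(),
                   pairs=np.stack([p, q], axis=1))

    @property
    def edge_count(self) -> int:
        return int(self.pairs.shape[0])

    def edge_voxels(self) -> np.ndarray:
        """(edge_count, 2) original in-mask voxel indices per edge."""
        return self.voxel_indices[self.pairs]

    def to_frame(self) -> pd.DataFrame:
        ev = self.edge_voxels()
        return pd.DataFrame(
            {"edge": np.arange(self.edge_count),
             "voxel_p": ev[:, 0], "voxel_q": ev[:, 1]}
        )


@dataclass
class FcVector:
    subject_id: str
    values: np.ndarray  # length edge_count, each in [-1, 1]
    edge_index: EdgeIndex


@dataclass
class GroupFcMatrix:
    group_label: str
    matrix: np.ndarray  # K_g x edge_count
    subject_ids: list[str]
    edge_index: EdgeIndex

    @property
    def n_subjects(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def edge_count(self) -> int:
        return int(self.matrix.shape[1])

    def to_frame(self) -> pd.DataFrame:
        ev = self.edge_index.edge_voxels()
        cols = [f"v{p}_v{q}" for p, q in ev]
        return pd.DataFrame(self.matrix, index=self.subject_ids, columns=cols)


def fc_vector(subject: SubjectMatrix, cavl12: VoxelSet) -> FcVector:
    """Pearson correlations of all joint-common-voxel pairs for one subject.

    Computed on the subject's (optionally band-passed) raw matrix, not on an
    ICA reconstruction; no Fisher transform — the raw r is the feature.
    """
    if cavl12.provenance != "joint_cavl12":
        raise ParameterError("fc_vector expects a joint_cavl12 voxel set")
    if subject.t_points < 3:
        raise DegenerateInputError("need at least 3 timepoints for correlations")
    series = subject.data[:, cavl12.indices]  # T x N12
    var = series.var(axis=0)
    if np.any(var <= 0):
        bad = cavl12.indices[np.flatnonzero(var <= 0)]
        raise DegenerateVoxelError(
            f"subject {subject.subject_id!r}: zero-variance series at joint "
            f"common voxel(s) {bad.tolist()}"
        )
    edge_index = EdgeIndex.from_voxel_set(cavl12)
    corr = np.corrcoef(series.T)
    values = np.clip(corr[edge_index.pairs[:, 0], edge_index.pairs[:, 1]], -1.0, 1.0)
    return FcVector(subject_id=subject.subject_id, values=values,
                    edge_index=edge_index)


def stack_group_fc(subjects: list[SubjectMatrix], cavl12: VoxelSet) -> GroupFcMatrix:
    """FC vectors of one cohort stacked row-wise in the given subject order."""
    if not subjects:
        raise GroupingError("empty subject list")
    labels = {s.group_label for s in subjects}
    if len(labels) != 1:
        raise GroupingError(f"mixed group labels: {sorted(labels)}")
    vectors = [fc_vector(s, cavl12) for s in subjects]
    return GroupFcMatrix(
        group_label=subjects[0].group_label,
        matrix=np.vstack([v.values for v in vectors]),
        subject_ids=[s.subject_id for s in subjects],
        edge_index=vectors[0].edge_index,
    )
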