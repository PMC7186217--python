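"""Activity-voxel sets: thresholding, intersections, region summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxelfc.activity import (
    VoxelSet,
    group_common_voxels,
    joint_common_voxels,
    subject_active_voxels,
    summarize_regions,
)
from voxelfc.decompose import ZMaps
from voxelfc.errors import PipelineDegenerateError, SpatialFrameError
from voxelfc.io_nifti import load_atlas

from conftest import make_full_mask


def zmaps_of(rows):
    return ZMaps(subject_id="s", z=np.atleast_2d(np.asarray(rows, float)))


def vset(indices, mask, provenance="group_cavl"):
    return VoxelSet(indices=np.asarray(indices, int), mask=mask,
                    provenance=provenance)


class TestSubjectActiveVoxels:
    def test_threshold_on_absolute_value(self):
        mask = make_full_mask((4, 1, 1))
        avl = subject_active_voxels(zmaps_of([0.0, 2.5, -3.0, 1.9]), 2.0, mask)
        assert avl.indices.tolist() == [1, 2]
        assert avl.provenance == "subject_avl"

    def test_union_over_components(self):
        mask = make_full_mask((3, 1, 1))
        z = zmaps_of([[2.1, 0, 0], [0, -2.2, 0]])
        assert subject_active_voxels(z, 2.0, mask).indices.tolist() == [0, 1]

    def test_threshold_inclusive(self):
        mask = make_full_mask((2, 1, 1))
        assert subject_active_voxels(zmaps_of([2.0, 1.999]), 2.0,
                                     mask).indices.tolist() == [0]

    def test_empty_set_warns(self):
        mask = make_full_mask((3, 1, 1))
        with pytest.warns(UserWarning, match="no active voxels"):
            avl = subject_active_voxels(zmaps_of([0.1, 0.2, 0.3]), 2.0, mask)
        assert avl.n == 0

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 3.0), st.floats(0.0, 1.5))
    def test_monotone_in_theta(self, seed, theta1, delta):
        rng = np.random.default_rng(seed)
        mask = make_full_mask((20, 1, 1))
        z = zmaps_of(rng.standard_normal((3, 20)) * 2)
        low = subject_active_voxels(z, theta1, mask)
        high = subject_active_voxels(z, theta1 + delta, mask)
        assert set(high.indices) <= set(low.indices)


class TestIntersections:
    def setup_method(self):
        self.mask = make_full_mask((10, 1, 1))

    def test_two_set_intersection(self):
        avls = [vset([1, 2, 3], self.mask, "subject_avl"),
                vset([2, 3, 4], self.mask, "subject_avl")]
        assert group_common_voxels(avls).indices.tolist() == [2, 3]

    def test_idempotent_and_order_independent(self):
        sets = [vset([1, 3, 5, 7], self.mask, "subject_avl")] * 4
        assert group_common_voxels(sets).indices.tolist() == [1, 3, 5, 7]
        a = [vset([1, 2, 3], self.mask, "subject_avl"),
             vset([2, 3, 4], self.mask, "subject_avl"),
             vset([3, 2, 9], self.mask, "subject_avl")]
        assert np.array_equal(group_common_voxels(a).indices,
                              group_common_voxels(a[::-1]).indices)

    def test_disjoint_sets_warn_empty(self):
        avls = [vset([1, 2], self.mask, "subject_avl"),
                vset([5, 6], self.mask, "subject_avl")]
        with pytest.warns(UserWarning):
            assert group_common_voxels(avls).n == 0

    def test_mask_mismatch(self):
        other = make_full_mask((9, 1, 1))
        with pytest.raises(SpatialFrameError):
            group_common_voxels([vset([1], self.mask, "subject_avl"),
                                 vset([1], other, "subject_avl")])

    def test_joint_intersection(self):
        j = joint_common_voxels(vset([2, 3, 7], self.mask),
                                vset([3, 7, 9], self.mask))
        assert j.indices.tolist() == [3, 7]
        assert j.provenance == "joint_cavl12"
        assert j.n == 2

    def test_joint_degenerate(self):
        with pytest.raises(PipelineDegenerateError):
            joint_common_voxels(vset([1], self.mask), vset([2], self.mask))

    def test_containment_chain(self, rng):
        avls1 = [vset(np.flatnonzero(rng.random(10) < 0.7), self.mask,
                      "subject_avl") for _ in range(4)]
        avls2 = [vset(np.flatnonzero(rng.random(10) < 0.7), self.mask,
                      "subject_avl") for _ in range(4)]
        c1, c2 = group_common_voxels(avls1), group_common_voxels(avls2)
        if c1.n and c2.n and np.intersect1d(c1.indices, c2.indices).size >= 2:
            j = joint_common_voxels(c1, c2)
            assert set(j.indices) <= set(c1.indices) <= set(avls1[0].indices)
            assert set(j.indices) <= set(c2.indices)


class TestSummarizeRegions:
    def make_atlas(self, mask, sizes):
        """Label contiguous runs of in-mask voxels 1..len(sizes)."""
        labels = np.zeros(mask.grid.n_grid_voxels, dtype=float)
        start = 0
        for i, size in enumerate(sizes, start=1):
            labels[start:start + size] = i
            start += size
        vol = labels.reshape(mask.grid.shape, order="F")
        return load_atlas(vol, mask)

    def test_both_thresholds_strict(self):
        mask = make_full_mask((200, 1, 1))
        atlas = self.make_atlas(mask, [100, 100])
        kept = summarize_regions(vset(range(11), mask), atlas)
        assert kept["label"].tolist() == [1]
        assert kept["voxel_number"].tolist() == [11]
        assert np.isclose(kept["voxel_ratio"].iloc[0], 0.11)
        # exactly 10 active -> excluded (strictly more than 10 required)
        excluded = summarize_regions(vset(range(10), mask), atlas)
        assert excluded.empty

    def test_fraction_threshold(self):
        mask = make_full_mask((60, 60, 2))
        atlas = self.make_atlas(mask, [5000, 100])
        # 12 active voxels in a 5000-voxel region: 0.24% < 1%
        summary = summarize_regions(vset(range(12), mask), atlas)
        assert summary.empty

    def test_centroid_in_world_mm(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        mask = make_full_mask((30, 1, 1), affine=affine)
        atlas = self.make_atlas(mask, [30])
        summary = summarize_regions(vset(range(12), mask), atlas,
                                    min_count=5, min_fraction=0.01)
        assert np.isclose(summary["x_mm"].iloc[0], 2.0 * np.mean(range(12)))
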