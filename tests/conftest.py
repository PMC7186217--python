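import numpy as np
import pytest

from voxelfc.io_nifti import BrainMask, SubjectMatrix, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_full_mask(shape=(4, 4, 4), affine=None):
    grid = VolumeGrid(shape=shape, affine=affine if affine is not None else np.eye(4))
    return BrainMask(grid, np.ones(shape, dtype=bool))


def make_subject(data, mask=None, subject_id="s0", group="A"):
    data = np.asarray(data, dtype=float)
    if mask is None:
        # a 1-D grid along x holding exactly V voxels
        mask = make_full_mask((data.shape[1], 1, 1))
    return SubjectMatrix(subject_id=subject_id, group_label=group,
                         data=data, mask=mask)


@pytest.fixture
def full_mask_4():
    return make_full_mask((4, 4, 4))


@pytest.fixture(scope="session")
def small_planted_fit():
    """One fitted model on a small planted dataset, shared across tests."""
    from voxelfc import EvalProtocol, SynthConfig, VoxelFC

    config = SynthConfig(subjects_per_cohort=(8, 8), seed=11)
    model = VoxelFC.from_synthetic(
        config, ica_runs=1, seed=7,
        protocol=EvalProtocol(n_runs=40, base_seed=2, positive_label="AD"),
    )
    return model, model.fit()
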