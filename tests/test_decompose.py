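"""MDL order selection, spatial ICA recovery, stability selection, z-maps."""

import numpy as np
import pytest

from voxelfc.decompose import (
    estimate_order_mdl,
    mdl_curve,
    run_spatial_ica,
    stability_select,
    zscore_maps,
)
from voxelfc.errors import DegenerateComponentError, ParameterError

from conftest import make_subject


def _mixture(rng, t_points, n_vox, k, noise_sd):
    """k sparse non-Gaussian spatial sources mixed by smooth time courses."""
    maps = np.zeros((k, n_vox))
    block = n_vox // k
    for j in range(k):
        maps[j, j * block:(j + 1) * block] = 1.0 + rng.random(block)
    courses = np.cumsum(rng.standard_normal((t_points, k)), axis=0)
    courses -= courses.mean(axis=0)
    courses /= courses.std(axis=0)
    data = courses @ maps + noise_sd * rng.standard_normal((t_points, n_vox))
    return data, maps, courses


def _mdl_oracle(data, max_order):
    """Independent MDL evaluation via SVD of the demeaned matrix."""
    x = data - data.mean(axis=0, keepdims=True)
    t_points, n_vox = x.shape
    s = np.linalg.svd(x, compute_uv=False)
    eig = np.zeros(t_points)
    eig[: s.size] = s**2 / n_vox
    eig = np.sort(np.clip(eig, 1e-300, None))
    best, best_val = None, np.inf
    for k in range(1, max_order + 1):
        tail = eig[: t_points - k]
        val = (
            -n_vox * (t_points - k)
            * (np.mean(np.log(tail)) - np.log(np.mean(tail)))
            + 0.5 * k * (2 * t_points - k) * np.log(n_vox)
        )
        if val < best_val:
            best, best_val = k, val
    return best


class TestMdl:
    def test_recovers_planted_order(self, rng):
        data, _, _ = _mixture(rng, 40, 2000, 3, noise_sd=0.01)
        subj = make_subject(data)
        assert estimate_order_mdl(subj, 20) == 3

    def test_rank_one_data(self, rng):
        course = rng.standard_normal(30)[:, None]
        spatial = rng.random(500)[None, :] + 0.5
        data = course @ spatial + 1e-6 * rng.standard_normal((30, 500))
        assert estimate_order_mdl(make_subject(data), 15) == 1

    def test_white_noise_low_order(self):
        for seed in range(10):
            data = np.random.default_rng(seed).standard_normal((30, 500))
            assert estimate_order_mdl(make_subject(data), 15) <= 3

    def test_matches_independent_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            k = int(rng.integers(1, 6))
            data, _, _ = _mixture(rng, 25, 300, k,
                                  noise_sd=float(rng.uniform(0.01, 0.2)))
            subj = make_subject(data)
            assert estimate_order_mdl(subj, 15) == _mdl_oracle(data, 15)

    def test_max_order_bound(self, rng):
        subj = make_subject(rng.standard_normal((20, 50)))
        with pytest.raises(ParameterError):
            estimate_order_mdl(subj, 20)


def _ica_mixture(rng, t_points, n_vox, k, noise_sd):
    """Independent sparse super-Gaussian spatial sources (valid ICA model:
    rows mutually uncorrelated, non-Gaussian)."""
    maps = rng.laplace(size=(k, n_vox))
    courses = np.cumsum(rng.standard_normal((t_points, k)), axis=0)
    courses -= courses.mean(axis=0)
    courses /= courses.std(axis=0)
    data = courses @ maps + noise_sd * rng.standard_normal((t_points, n_vox))
    return data, maps, courses


def _greedy_match_abs_corr(true_maps, est_maps):
    """Greedy absolute-correlation assignment; returns matched |r| values."""
    remaining = list(range(est_maps.shape[0]))
    scores = []
    for t in true_maps:
        best_r, best_j = -1.0, None
        for j in remaining:
            r = abs(np.corrcoef(t, est_maps[j])[0, 1])
            if r > best_r:
                best_r, best_j = r, j
        scores.append(best_r)
        remaining.remove(best_j)
    return np.array(scores)


class TestSpatialIca:
    def test_recovers_nongaussian_sources(self, rng):
        data, maps, _ = _ica_mixture(rng, 60, 1500, 3, noise_sd=1e-8)
        dec = run_spatial_ica(make_subject(data), 3, seed=0)
        assert np.all(_greedy_match_abs_corr(maps, dec.spatial_maps) > 0.99)

    def test_rank_one_identity_up_to_scale(self, rng):
        course = rng.standard_normal(40)[:, None]
        spatial = (rng.random(800) > 0.7).astype(float)
        data = course @ spatial[None, :]
        dec = run_spatial_ica(make_subject(data), 1, seed=3)
        r = np.corrcoef(spatial, dec.spatial_maps[0])[0, 1]
        assert abs(r) > 0.999

    def test_deterministic_given_seed(self, rng):
        data, _, _ = _mixture(rng, 40, 600, 3, noise_sd=0.05)
        subj = make_subject(data)
        d1 = run_spatial_ica(subj, 3, seed=42)
        d2 = run_spatial_ica(subj, 3, seed=42)
        assert np.array_equal(d1.spatial_maps, d2.spatial_maps)
        assert np.array_equal(d1.mixing, d2.mixing)

    def test_rows_pairwise_decorrelated(self, rng):
        data, _, _ = _mixture(rng, 50, 1000, 4, noise_sd=0.05)
        dec = run_spatial_ica(make_subject(data), 4, seed=1)
        corr = np.corrcoef(dec.spatial_maps)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6

    def test_reconstruction_matches_rank_k_projection(self, rng):
        data, _, _ = _ica_mixture(rng, 40, 600, 3, noise_sd=0.02)
        subj = make_subject(data)
        dec = run_spatial_ica(subj, 3, seed=0)
        recon = dec.mixing @ dec.spatial_maps
        # the estimation centers voxels over time and timepoints over voxels
        x = data - data.mean(axis=0, keepdims=True)
        x = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        proj = u[:, :3] @ np.diag(s[:3]) @ vt[:3]
        assert np.allclose(recon, proj, atol=1e-5 * np.abs(proj).max())


class TestStabilitySelect:
    def test_stable_problem_has_high_stability(self, rng):
        data, maps, _ = _ica_mixture(rng, 60, 1200, 3, noise_sd=1e-8)
        subj = make_subject(data)
        dec = stability_select(subj, 3, n_runs=5, base_seed=0, bootstrap=True)
        assert dec.stability_index is not None
        assert np.all(dec.stability_index > 0.95)
        assert np.all(_greedy_match_abs_corr(maps, dec.spatial_maps) > 0.99)

    def test_single_run_degrades_to_plain_ica(self, rng):
        data, _, _ = _mixture(rng, 40, 600, 3, noise_sd=0.05)
        subj = make_subject(data)
        plain = run_spatial_ica(subj, 3, seed=9)
        stab = stability_select(subj, 3, n_runs=1, base_seed=9)
        assert stab.stability_index is None
        assert np.array_equal(plain.spatial_maps, stab.spatial_maps)


class TestZscoreMaps:
    def test_known_values(self):
        from voxelfc.decompose import IcaDecomposition

        dec = IcaDecomposition("s", 1, np.array([[1.0, 2.0, 3.0, 4.0]]),
                               np.zeros((5, 1)), seed=0)
        z = zscore_maps(dec).z[0]
        assert np.allclose(z, [-1.3416, -0.4472, 0.4472, 1.3416], atol=1e-4)

    def test_idempotent_and_normalized(self, rng):
        from voxelfc.decompose import IcaDecomposition

        maps = rng.standard_normal((3, 200))
        dec = IcaDecomposition("s", 3, maps, np.zeros((5, 3)), seed=0)
        z1 = zscore_maps(dec).z
        dec2 = IcaDecomposition("s", 3, z1, np.zeros((5, 3)), seed=0)
        z2 = zscore_maps(dec2).z
        assert np.allclose(z1, z2, atol=1e-12)
        assert np.all(np.abs(z1.mean(axis=1)) < 1e-8)
        assert np.all(np.abs(z1.std(axis=1) - 1) < 1e-6)

    def test_constant_map_rejected(self):
        from voxelfc.decompose import IcaDecomposition

        dec = IcaDecomposition("s", 1, np.ones((1, 10)), np.zeros((5, 1)), seed=0)
        with pytest.raises(DegenerateComponentError):
            zscore_maps(dec)
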