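"""Edge-wise t-tests, BH-FDR adjustment and differential-FC selection."""

import numpy as np
import pytest

from voxelfc.activity import VoxelSet
from voxelfc.diffstats import (
    aggregate_dfc_by_region,
    edgewise_ttest,
    fdr_adjust,
    select_dfc,
)
from voxelfc.errors import ParameterError, SampleSizeError
from voxelfc.io_nifti import load_atlas

from conftest import make_full_mask


def bh_select_oracle(p, alpha):
    """Brute-force BH step-up: largest i with p_(i) <= (i/m) alpha; select
    all p at or below that order statistic."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    cutoff_i = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= i / m * alpha:
            cutoff_i = i
    if cutoff_i == 0:
        return np.zeros(m, dtype=bool)
    return p <= sorted_p[cutoff_i - 1]


class TestEdgewiseTtest:
    def test_hand_computed_pooled_t(self):
        a = np.array([[0.1], [0.2], [0.3], [0.4]])
        b = np.array([[0.5], [0.6], [0.7], [0.8]])
        t, p, degen = edgewise_ttest(a, b)
        # pooled-variance oracle: s2 = 1/60, se = sqrt(s2 * 1/2), df = 6
        assert np.isclose(t[0], -4.3818, atol=1e-4)
        assert np.isclose(p[0], 0.00466, atol=2e-5)
        assert degen.size == 0

    def test_null_identity(self, rng):
        x = rng.standard_normal((5, 10))
        t, p, _ = edgewise_ttest(x, x.copy())
        assert np.allclose(t, 0.0) and np.allclose(p, 1.0)

    def test_antisymmetry(self, rng):
        a = rng.standard_normal((6, 20))
        b = rng.standard_normal((8, 20))
        t1, p1, _ = edgewise_ttest(a, b)
        t2, p2, _ = edgewise_ttest(b, a)
        assert np.allclose(t1, -t2) and np.allclose(p1, p2)

    def test_zero_pooled_variance_cases(self):
        a = np.tile([1.0, 2.0], (3, 1))
        b = np.tile([1.0, 5.0], (3, 1))
        t, p, degen = edgewise_ttest(a, b)
        assert t[0] == 0.0 and p[0] == 1.0  # equal means
        assert p[1] == 0.0 and degen.tolist() == [1]  # unequal means

    def test_group_size_guard(self, rng):
        with pytest.raises(SampleSizeError):
            edgewise_ttest(rng.standard_normal((1, 4)),
                           rng.standard_normal((5, 4)))

    def test_matches_scipy_on_random_data(self, rng):
        from scipy import stats

        a = rng.standard_normal((7, 30))
        b = rng.standard_normal((9, 30)) + 0.3
        t, p, _ = edgewise_ttest(a, b)
        ref = stats.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.allclose(t, ref.statistic, atol=1e-12)
        assert np.allclose(p, ref.pvalue, atol=1e-12)


class TestFdrAdjust:
    def test_step_up_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.03, 0.5])
        adj = fdr_adjust(p)
        assert (adj < 0.05).tolist() == [True, True, True, True, False]

    def test_all_ones_and_single(self):
        assert np.allclose(fdr_adjust(np.ones(7)), 1.0)
        assert np.allclose(fdr_adjust(np.array([0.37])), [0.37])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(40)
        assert np.all(fdr_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fdr_adjust(np.array([0.1, 1.2]))

    def test_matches_brute_force_oracle_on_100_vectors(self):
        alpha = 0.05
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(1, 51))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            selected = fdr_adjust(p) < alpha
            assert np.array_equal(selected, bh_select_oracle(p, alpha)), seed


class TestSelectDfc:
    def test_default_alpha_and_pure_selection(self, rng):
        a = rng.standard_normal((10, 15))
        b = rng.standard_normal((10, 15))
        b[:, 3] += 5.0
        res = select_dfc(a, b)
        assert res.alpha == 0.05
        assert 3 in res.dfci
        # selected columns are the raw FC columns, untransformed
        assert np.array_equal(res.dfc1, a[:, res.dfci])
        assert np.array_equal(res.dfc2, b[:, res.dfci])

    def test_null_gives_empty_outcome(self, rng):
        x = rng.standard_normal((8, 12))
        res = select_dfc(x, x.copy())
        assert res.is_empty and res.dfc1.shape == (8, 0)

    def test_planted_shift_monte_carlo(self):
        """One edge with a 0.5 shift in r units among 99 nulls, 30 per
        group: the planted edge is selected and false selections stay below
        5% of nulls on average."""
        hits, false_fracs = 0, []
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            a = 0.15 * rng.standard_normal((30, 100))
            b = 0.15 * rng.standard_normal((30, 100))
            b[:, 0] += 0.5
            res = select_dfc(a, b)
            # cross-check the whole selection against independent oracles
            t_ref = _oracle_t(a, b)
            p_ref = 2 * _t_sf(np.abs(t_ref), 58)
            ref_sel = np.flatnonzero(bh_select_oracle(p_ref, 0.05))
            assert np.array_equal(res.dfci, ref_sel)
            hits += int(0 in res.dfci)
            false_fracs.append(np.sum(res.dfci != 0) / 99)
        assert hits == n_seeds
        assert np.mean(false_fracs) <= 0.05

    def test_fisher_z_option_keeps_raw_features(self, rng):
        a = np.clip(0.3 * rng.standard_normal((10, 8)), -0.9, 0.9)
        b = np.clip(0.3 * rng.standard_normal((10, 8)) + 0.6, -0.9, 0.9)
        res = select_dfc(a, b, fisher_z=True)
        if not res.is_empty:
            assert np.array_equal(res.dfc2, b[:, res.dfci])


def _oracle_t(a, b):
    n1, n2 = a.shape[0], b.shape[0]
    s2 = ((n1 - 1) * a.var(0, ddof=1) + (n2 - 1) * b.var(0, ddof=1)) / (n1 + n2 - 2)
    return (a.mean(0) - b.mean(0)) / np.sqrt(s2 * (1 / n1 + 1 / n2))


def _t_sf(x, df):
    from scipy import special

    return 0.5 * special.betainc(df / 2, 0.5, df / (df + x**2))


class TestAggregateByRegion:
    def make_setup(self):
        mask = make_full_mask((12, 1, 1))
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2, 0, 0, 0, 0], float)
        atlas = load_atlas(labels.reshape((12, 1, 1), order="F"), mask,
                           names={1: "A", 2: "B"})
        cavl = VoxelSet(indices=np.array([0, 1, 4, 5, 8]), mask=mask,
                        provenance="joint_cavl12")
        return mask, atlas, cavl

    def run_with_dfci(self, dfci):
        import numpy as np

        from voxelfc.diffstats import DiffFcResult

        mask, atlas, cavl = self.make_setup()
        m = cavl.n * (cavl.n - 1) // 2
        res = DiffFcResult(
            t_stats=np.zeros(m), p_raw=np.ones(m), p_adj=np.ones(m),
            dfci=np.asarray(dfci, int), alpha=0.05,
            dfc1=np.zeros((2, len(dfci))), dfc2=np.zeros((2, len(dfci))),
        )
        return aggregate_dfc_by_region(res, cavl, atlas)

    def test_cross_region_counts(self):
        # cavl positions: 0,1 -> A; 2,3 -> B; 4 -> unlabeled
        # edges (lexicographic over 5 positions): 0:(0,1) 1:(0,2) 2:(0,3)
        # 3:(0,4) 4:(1,2) 5:(1,3) 6:(1,4) 7:(2,3) 8:(2,4) 9:(3,4)
        table = self.run_with_dfci([1, 2, 4])  # three A-B edges
        assert table.loc["A", "B"] == 3 and table.loc["B", "A"] == 3

    def test_within_region_on_diagonal(self):
        table = self.run_with_dfci([0, 7])
        assert table.loc["A", "A"] == 1 and table.loc["B", "B"] == 1

    def test_unlabeled_pseudo_region_and_empty(self):
        table = self.run_with_dfci([3])
        assert table.loc["A", "unlabeled"] == 1
        empty = self.run_with_dfci([])
        assert int(empty.to_numpy().sum()) == 0
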