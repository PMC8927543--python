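"""Statistical endpoints: summary tests, GLM, TFCE, permutation FWE, clusters."""

import numpy as np
import pytest
from scipy import ndimage, stats

from hubdisrupt.inference import (
    bonferroni_threshold,
    chi_square_2x2,
    extract_clusters,
    glm_tstat_map,
    partial_spearman,
    permutation_fwe,
    rfma_ratio,
    rm_ancova_group,
    tfce_transform,
    welch_t_from_summary,
)


class TestRecoveryRatio:
    @pytest.mark.parametrize(
        "base,follow,expect", [(30, 45, 0.5), (40, 40, 0.0), (40, 30, -0.25)]
    )
    def test_values(self, base, follow, expect):
        assert rfma_ratio(base, follow) == pytest.approx(expect)

    def test_undefined_at_zero_baseline(self):
        with pytest.raises(ValueError):
            rfma_ratio(0, 10)


class TestSummaryTests:
    def test_identical_groups_null(self):
        t, _, p = welch_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_matches_scipy(self, rng):
        for _ in range(10):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(5, 40, 2)
            t, df, p = welch_t_from_summary(m1, s1, int(n1), m2, s2, int(n2))
            ref = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_chi2_matches_scipy(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(1, 40, 4)
            chi2, p = chi_square_2x2(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_proportional_table_null(self):
        chi2, p = chi_square_2x2(10, 20, 5, 10)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 10)

    @pytest.mark.parametrize("alpha,m,expect", [(0.05, 8, 0.00625), (0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_bonferroni(self, alpha, m, expect):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expect)


class TestRmAncova:
    def _cohort(self, rng, n=30, offset=0.0):
        group = np.r_[np.zeros(n), np.ones(n)]
        age = rng.uniform(45, 80, 2 * n)
        gender = rng.integers(0, 2, 2 * n)
        kd = rng.standard_normal((2 * n, 10)) + offset * group[:, None]
        return kd, group, age, gender

    def test_single_density_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        kd, group, age, gender = self._cohort(rng, n=15, offset=0.4)
        f, df, p = rm_ancova_group(kd[:, :1], group, age, gender)
        x = sm.add_constant(np.column_stack([group, age, gender]))
        fit = sm.OLS(kd[:, 0], x).fit()
        ref = fit.f_test(np.array([0.0, 1.0, 0.0, 0.0]))
        assert f == pytest.approx(float(ref.fvalue), abs=1e-8)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-8)
        assert df == (1, 2 * 15 - 4)

    def test_power_for_one_sd_offset(self):
        rejections = 0
        for k in range(60):
            rng = np.random.default_rng(3000 + k)
            kd, group, age, gender = self._cohort(rng, n=30, offset=1.0)
            _, _, p = rm_ancova_group(kd, group, age, gender)
            rejections += p < 0.05
        assert rejections >= 54  # > 0.9 power

    def test_rejects_tiny_groups(self, rng):
        kd = rng.standard_normal((4, 10))
        with pytest.raises(ValueError):
            rm_ancova_group(kd, np.array([0, 0, 1, 1]), np.arange(4), np.zeros(4))


class TestPartialSpearman:
    def test_monotone_transform_invariance(self):
        x = np.linspace(-2, 2, 20)
        rho, p = partial_spearman(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_tied_toy_matches_scipy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([5.0, 6, 7, 8, 7])
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert rho == pytest.approx(0.8208, abs=1e-4)

    def test_ties_free_exact_match_with_scipy(self, rng):
        for _ in range(5):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            rho, p = partial_spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_confound_adjustment_removes_spurious_association(self):
        rhos = []
        for k in range(300):
            rng = np.random.default_rng(5000 + k)
            confound = rng.standard_normal(200)
            x = confound + rng.standard_normal(200)
            y = confound + rng.standard_normal(200)
            rho, _ = partial_spearman(x, y, confound[:, None])
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_rejects_constant_input(self):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(10), np.arange(10.0))


class TestGlmTstat:
    def test_matches_per_voxel_oracle(self, rng):
        import statsmodels.api as sm

        n, v = 25, 8
        design = np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.uniform(40, 80, n), rng.integers(0, 2, n)]
        )
        maps = rng.standard_normal((n, v))
        t = glm_tstat_map(maps, design, np.array([0, 1.0, 0, 0]))
        for j in range(v):
            fit = sm.OLS(maps[:, j], design).fit()
            assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_zero_contrast_zero_map(self, rng):
        n = 12
        design = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        t = glm_tstat_map(rng.standard_normal((n, 5)), design, np.array([0.0, 0.0]))
        np.testing.assert_allclose(t, 0.0)

    def test_noise_free_effect_saturates(self):
        n = 10
        group = np.r_[np.zeros(5), np.ones(5)]
        design = np.column_stack([np.ones(n), group])
        maps = np.zeros((n, 3))
        maps[:, 1] = group * 2.0  # exact separation, zero residual
        t = glm_tstat_map(maps, design, np.array([0.0, 1.0]))
        assert t[1] > 1e6  # saturated: residual variance is (numerically) zero
        np.testing.assert_allclose(t[[0, 2]], 0.0)


def tfce_oracle(arr, e=0.5, h=2.0, n_steps=100, connectivity=26):
    """Explicit per-threshold connected-component summation (positive side)."""
    arr = np.asarray(arr, float)
    pos = np.maximum(arr, 0.0)
    out = np.zeros_like(pos)
    vmax = pos.max()
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    for k in range(1, n_steps + 1):
        thr = k * dh
        labels, _ = ndimage.label(pos >= thr, structure=structure)
        sizes = np.bincount(labels.ravel())
        m = labels > 0
        out[m] += sizes[labels[m]] ** e * thr**h * dh
    return out


class TestTfce:
    def test_zero_map_zero_output(self):
        np.testing.assert_array_equal(tfce_transform(np.zeros((4, 4, 4))), 0.0)

    def test_single_voxel_matches_discrete_sum(self):
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 3.0
        got = tfce_transform(arr)
        dh = 3.0 / 100
        expect = sum(1.0**0.5 * (k * dh) ** 2 * dh for k in range(1, 101))
        assert got[2, 2, 2] == pytest.approx(expect, rel=1e-12)
        # approaches h^3/3 as dh -> 0
        assert got[2, 2, 2] == pytest.approx(27 / 3, rel=0.02)

    def test_1d_two_peak_toy_matches_oracle(self):
        arr = np.zeros((12, 1, 1))
        arr[[1, 2, 3], 0, 0] = [1.0, 2.0, 1.0]
        arr[[7, 8], 0, 0] = [3.0, 1.5]
        np.testing.assert_allclose(tfce_transform(arr), tfce_oracle(arr), atol=1e-9)

    def test_3d_random_matches_oracle_both_signs(self, rng):
        arr = rng.standard_normal((6, 6, 6))
        got = tfce_transform(arr)
        expect = tfce_oracle(arr) - tfce_oracle(-arr)
        np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_monotone_under_uniform_scaling(self, rng):
        arr = np.abs(rng.standard_normal((5, 5, 5)))
        assert np.all(tfce_transform(2.0 * arr) >= tfce_transform(arr) - 1e-12)

    def test_connectivity_modes_differ_on_diagonal_pair(self):
        arr = np.zeros((3, 3, 3))
        arr[0, 0, 0] = arr[1, 1, 1] = 1.0
        full = tfce_transform(arr, connectivity=26)
        face = tfce_transform(arr, connectivity=6)
        assert full[0, 0, 0] > face[0, 0, 0]  # joined only under 26-connectivity


def _grid_coords(v, shape):
    return np.argwhere(np.ones(shape, bool))[:v]


class TestPermutationFwe:
    def _setup(self, rng, n=16, shape=(4, 4, 4), effect=0.0):
        v = int(np.prod(shape))
        coords = _grid_coords(v, shape)
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        design = np.column_stack(
            [np.ones(n), group, rng.uniform(45, 80, n), rng.integers(0, 2, n)]
        )
        maps = rng.standard_normal((n, v))
        if effect:
            block = (coords[:, 0] < 2) & (coords[:, 1] < 2) & (coords[:, 2] < 2)
            maps[n // 2 :, block] += effect
        return maps, design, coords

    def test_same_seed_identical_p_maps(self, rng):
        maps, design, coords = self._setup(rng)
        contrast = np.array([0, 1.0, 0, 0])
        r1 = permutation_fwe(maps, design, contrast, coords, (4, 4, 4), n_perm=100, seed=5)
        r2 = permutation_fwe(maps, design, contrast, coords, (4, 4, 4), n_perm=100, seed=5)
        np.testing.assert_array_equal(r1["pos"].p_fwe, r2["pos"].p_fwe)

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(0)
        maps, design, coords = self._setup(rng, n=24, effect=2.5)
        res = permutation_fwe(
            maps, design, np.array([0, 1.0, 0, 0]), coords, (4, 4, 4), n_perm=300, seed=1
        )
        block = (coords[:, 0] < 2) & (coords[:, 1] < 2) & (coords[:, 2] < 2)
        assert (res["pos"].p_fwe[block] < 0.05).mean() >= 0.95
        assert (res["neg"].p_fwe < 0.05).sum() == 0

    def test_exhaustive_enumeration_for_tiny_cohort(self, rng):
        v = 8
        coords = _grid_coords(v, (2, 2, 2))
        maps = rng.standard_normal((4, v))
        design = np.column_stack([np.ones(4), np.array([0, 0, 1, 1.0])])
        with pytest.warns(RuntimeWarning, match="exhaustively"):
            res = permutation_fwe(
                maps, design, np.array([0, 1.0]), coords, (2, 2, 2), n_perm=500, seed=0
            )
        assert res["pos"].n_perm == 24  # 4!


class TestClusterTable:
    def test_empty_when_nothing_significant(self):
        coords = _grid_coords(8, (2, 2, 2))
        table = extract_clusters(np.zeros(8), np.ones(8), coords, (2, 2, 2))
        assert table.empty

    def test_three_voxel_cluster_volume_on_6mm_grid(self):
        shape = (4, 4, 4)
        coords = _grid_coords(64, shape)
        p = np.ones(64)
        stat = np.zeros(64)
        idx = [0, 1, 2]  # (0,0,0),(0,0,1),(0,0,2): one 26-connected component
        for i, s in zip(idx, [3.0, 4.0, 3.5]):
            p[i] = 0.01
            stat[i] = s
        table = extract_clusters(stat, p, coords, shape, voxel_size=6.0)
        assert len(table) == 1
        assert table.loc[0, "n_voxels"] == 3
        assert table.loc[0, "volume_mm3"] == pytest.approx(648.0)
        assert table.loc[0, "peak_stat"] == pytest.approx(4.0)

    def test_separate_components_reported_separately(self):
        shape = (5, 5, 5)
        coords = _grid_coords(125, shape)
        p = np.ones(125)
        grid_index = {tuple(c): i for i, c in enumerate(coords)}
        comp_a = [(0, 0, 0), (0, 0, 1)]
        comp_b = [(4, 4, 4), (4, 4, 3)]
        for c in comp_a + comp_b:
            p[grid_index[c]] = 0.01
        table = extract_clusters(np.ones(125), p, coords, shape)
        assert len(table) == 2
        assert sorted(table["n_voxels"]) == [2, 2]
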