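"""Statistics battery: PCA, repeated-measures ANOVA, Kruskal-Wallis, Bonferroni."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dims_stability as ds
from dims_stability.stats import rm_anova_matrix


def oracle_rm_anova(grid: np.ndarray) -> float:
    """From-scratch one-way within-subjects F via explicit sums of squares."""
    n, k = grid.shape
    grand = grid.mean()
    ss_cond = n * sum((grid[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (
                grid[i, j] - grid[i].mean() - grid[:, j].mean() + grand
            ) ** 2
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestPca:
    def test_collinear_samples_single_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = pd.DataFrame([base * t for t in (1.0, 2.0, 3.0)])
        res = ds.pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(4, 6)))
        X = pd.concat([X, X.iloc[[1]]], ignore_index=True)
        res = ds.pca(X)
        np.testing.assert_allclose(
            res.scores.iloc[1].to_numpy(), res.scores.iloc[-1].to_numpy(), atol=1e-10
        )

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(10, 20)))
        res = ds.pca(X)
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - centered).max() < 1e-8

    def test_loadings_orthonormal_and_variance_nonincreasing(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(8, 5)))
        res = ds.pca(X)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_constant_matrix_handled(self):
        X = pd.DataFrame(np.ones((5, 4)))
        res = ds.pca(X)
        assert np.allclose(res.explained_variance, 0.0)


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            grid = rng.normal(size=(3, 4))
            got = ds.rm_anova(grid)
            assert got.statistic == pytest.approx(oracle_rm_anova(grid), abs=1e-10)

    def test_two_levels_equals_squared_paired_t(self):
        rng = np.random.default_rng(11)
        grid = rng.normal(size=(6, 2))
        got = ds.rm_anova(grid)
        t, p = sps.ttest_rel(grid[:, 0], grid[:, 1])
        assert got.statistic == pytest.approx(t**2, rel=1e-10)
        assert got.p_raw == pytest.approx(p, rel=1e-10)

    def test_all_equal_flagged_degenerate_f_zero(self):
        got = ds.rm_anova(np.ones((3, 4)))
        assert got.statistic == 0.0
        assert got.degenerate
        assert got.p_raw == 1.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        grid = rng.normal(size=(4, 3))
        long = pd.DataFrame(
            {
                "y": grid.ravel(),
                "subject": np.repeat(np.arange(4), 3),
                "level": np.tile(np.arange(3), 4),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="level", subject="subject")
        got = ds.rm_anova(grid)
        assert got.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert got.p_raw == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_vectorized_matches_per_feature(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(20, 3, 5))
        res = rm_anova_matrix(x)
        for i in range(20):
            assert res["F"][i] == pytest.approx(oracle_rm_anova(x[i]), abs=1e-10)

    def test_too_small_grids_rejected(self):
        with pytest.raises(ValueError):
            ds.rm_anova(np.ones((1, 4)))
        with pytest.raises(ValueError):
            ds.rm_anova(np.ones((3, 1)))


class TestKruskalWallis:
    def test_hand_computed_h(self):
        got = ds.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert got.statistic == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups_h_zero_after_tie_correction(self):
        got = ds.kruskal_wallis([1, 2], [1, 2])
        assert got.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_values_h_zero(self):
        got = ds.kruskal_wallis([2, 2, 2], [2, 2, 2])
        assert got.statistic == 0.0
        assert got.p_raw == 1.0

    def test_minimum_attainable_p_three_vs_three(self):
        got = ds.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert got.p_raw == pytest.approx(0.0495, abs=5e-4)

    def test_p_sandwiched_by_exhaustive_permutation(self):
        """chi2 p lies between the strict and non-strict permutation tails."""
        rng = np.random.default_rng(14)
        for _ in range(10):
            pooled = rng.normal(size=6)
            a, b = pooled[:3], pooled[3:]
            got = ds.kruskal_wallis(a, b)
            h_obs = got.statistic
            hs = []
            for comb in itertools.combinations(range(6), 3):
                rest = [i for i in range(6) if i not in comb]
                hs.append(ds.kruskal_wallis(pooled[list(comb)], pooled[rest]).statistic)
            hs = np.asarray(hs)
            p_strict = float((hs > h_obs + 1e-12).mean())
            p_nonstrict = float((hs >= h_obs - 1e-12).mean())
            assert p_strict - 1e-9 <= got.p_raw <= p_nonstrict + 1e-9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ds.kruskal_wallis([], [1.0])


class TestBonferroni:
    def test_multiplication_and_clamp(self):
        got = ds.bonferroni([1e-5, 0.5], m=1852)
        assert got[0] == pytest.approx(0.01852)
        assert got[1] == 1.0

    def test_identity_at_family_size_one(self):
        assert ds.bonferroni([0.3], m=1).tolist() == [0.3]

    def test_order_preserved(self):
        p = [0.2, 0.01, 0.8]
        got = ds.bonferroni(p, m=3)
        assert np.argsort(got).tolist() == np.argsort(p).tolist()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ds.bonferroni([1.5], m=1)
        with pytest.raises(ValueError):
            ds.bonferroni([0.1, 0.2], m=1)


class TestFeatureTests:
    def test_runs_both_tests_per_feature(self, tiny_library, small_design, noise_free_matrix):
        out = ds.feature_tests(noise_free_matrix, small_design, "freeze_thaw")
        assert set(out["test"]) == {"rm_anova", "kruskal_wallis"}
        assert len(out) == 2 * len(tiny_library)
        assert ((out["p_bonferroni"] >= out["p_raw"] - 1e-15) | out["p_raw"].isna()).all()

    def test_excluded_cells_drop_levels_when_pools_scarce(self, tiny_library):
        # cycle-1 and cycle-7 samples of two different pools are excluded:
        # complete-pool ANOVA would keep < 2 pools, so the two levels are
        # dropped instead and all three pools retained
        design = ds.generate_design(3, {"freeze_thaw": [1, 4, 7]}, 2).exclude(
            ["P2_freeze_thaw_1", "P1_freeze_thaw_7"]
        )
        peaks = ds.simulate_peak_tables(
            tiny_library, design, ds.EffectSpec(noise_sigma=0.1, seed=1)
        )
        ann = ds.summed_intensities(
            ds.match_peaks(peaks, tiny_library), tiny_library, design
        )
        out = ds.feature_tests(ann, design, "freeze_thaw")
        anova = out[out["test"] == "rm_anova"]
        # reference + cycle 4 survive: df1 = k - 1 = 1, df2 = (k-1)(n-1) = 2
        assert (anova["df1"] == 1).all()
        assert (anova["df2"] == 2).all()

    def test_family_size_override(self, small_design, noise_free_matrix):
        out = ds.feature_tests(noise_free_matrix, small_design, "room", family_m=1852)
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, 1852 * out["p_raw"])
        )
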