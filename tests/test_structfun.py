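"""Tract features, adjusted correlations, FWER screen, PC1 pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neonoci.images import VoxelMap
from neonoci.structfun import (
    CONFIRMED_TRACTS,
    TRACTS,
    adjusted_correlation,
    compare_tract_profiles,
    confirmatory_test,
    exploratory_screen,
    md_pc1,
    qc_threshold_map,
    subset_combination_analysis,
    tract_mean,
)


class TestQcThreshold:
    def test_mk_above_range_removed(self):
        data = np.full((3, 3, 3), 1.0)
        data[0, 0, 0] = 3.5
        cleaned, removed = qc_threshold_map(VoxelMap(data), "MK")
        assert removed == 1
        assert not cleaned.mask[0, 0, 0]

    def test_valid_md_map_untouched(self):
        cleaned, removed = qc_threshold_map(VoxelMap(np.full((3, 3, 3), 1.2)), "MD")
        assert removed == 0
        assert cleaned.mask.all()

    def test_fa_out_of_range_counted(self):
        data = np.full((3, 3, 3), 0.5)
        data[0, 0, 0] = 1.2
        data[1, 1, 1] = -0.1
        _, removed = qc_threshold_map(VoxelMap(data), "FA")
        assert removed == 2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            qc_threshold_map(VoxelMap(np.zeros((3, 3, 3))), "AD")


class TestTractMean:
    def test_probability_threshold_excludes_low_voxels(self):
        param = VoxelMap(np.full((3, 3, 3), 2.0))
        prob = np.full((3, 3, 3), 0.005)
        prob[0] = 0.5
        param.data[0] = 7.0
        assert tract_mean(param, VoxelMap(prob), 0.01) == pytest.approx(7.0)

    def test_uniform_value(self):
        param = VoxelMap(np.full((3, 3, 3), 1.3))
        prob = VoxelMap(np.full((3, 3, 3), 0.8))
        assert tract_mean(param, prob) == pytest.approx(1.3)

    def test_matches_masked_mean_oracle(self, rng):
        data = rng.normal(size=(5, 5, 5))
        prob = rng.random((5, 5, 5))
        got = tract_mean(VoxelMap(data), VoxelMap(prob), 0.3)
        assert got == pytest.approx(data[prob >= 0.3].mean(), abs=1e-12)

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError):
            tract_mean(VoxelMap(np.zeros((3, 3, 3))),
                       VoxelMap(np.zeros((3, 3, 3))), 0.5)


class TestAdjustedCorrelation:
    def test_no_confounds_is_plain_pearson(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert adjusted_correlation(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_single_confound_matches_partial_correlation_formula(self, rng):
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 30))
            x = x + 0.5 * z
            y = y - 0.3 * z
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
            assert adjusted_correlation(x, y, z) == pytest.approx(oracle, abs=1e-10)

    def test_confound_equal_to_variable_rejected(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        with pytest.raises(ValueError, match="zero-variance residual"):
            adjusted_correlation(x, y, x)


def _feature_frame(rng, n, m_informative=0, y=None, effect=0.0):
    cols = {}
    for t in TRACTS:
        for p in ("MD", "FA", "MK"):
            cols[f"{t}_{p}"] = rng.normal(size=n)
    F = pd.DataFrame(cols)
    if m_informative and y is not None:
        for t in CONFIRMED_TRACTS[:m_informative]:
            F[f"{t}_MD"] = effect * y + np.sqrt(1 - effect ** 2) * rng.normal(size=n)
    return F


class TestExploratoryScreen:
    def test_counts_48_tests_and_fwer_dominance(self, rng):
        n = 40
        y = rng.normal(size=n)
        F = _feature_frame(rng, n)
        Z = rng.normal(size=(n, 3))
        res = exploratory_screen(y, F, Z, n_perm=200, seed=1)
        assert len(res.table) == 48
        assert np.all(res.table["fwer_p"].to_numpy()
                      >= res.table["p"].to_numpy() - 1e-12)

    def test_matches_per_feature_loop_oracle(self, rng):
        """Vectorised adjusted correlations equal feature-by-feature calls."""
        n = 25
        y = rng.normal(size=n)
        F = _feature_frame(rng, n)
        Z = rng.normal(size=(n, 2))
        res = exploratory_screen(y, F, Z, n_perm=50, seed=2)
        for col, r in zip(F.columns, res.table["r"]):
            assert r == pytest.approx(adjusted_correlation(F[col], y, Z),
                                      abs=1e-10)

    def test_injected_association_power_matches_fisher_z(self):
        """An injected |adjusted r| = 0.3 at n = 215 survives the 48-test
        max-statistic FWER screen at the Fisher-z analytic rate: with
        independent features the max-stat critical value is ~Bonferroni,
        |r|_crit = tanh(z_{1-0.05/96}/sqrt(n-3)) = 0.221, giving power
        Phi((atanh(0.3) - atanh(0.221)) sqrt(n-3)) = 0.89."""
        from scipy import stats as sps
        n, n_seeds = 215, 60
        analytic = float(sps.norm.sf(
            sps.norm.isf(0.05 / 48 / 2) - np.arctanh(0.3) * np.sqrt(n - 3)))
        hits = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=n)
            F = _feature_frame(rng, n)
            F["atr_MD"] = 0.3 * (y - y.mean()) / y.std() + np.sqrt(1 - 0.09) \
                * rng.normal(size=n)
            res = exploratory_screen(y, F, None, n_perm=300, seed=seed)
            row = res.table[(res.table["tract"] == "atr")
                            & (res.table["parameter"] == "MD")]
            hits += bool(row["significant"].iloc[0])
        se = np.sqrt(analytic * (1 - analytic) / n_seeds)
        assert abs(hits / n_seeds - analytic) <= 3 * se + 0.02

    def test_missing_rows_rejected(self, rng):
        n = 20
        F = _feature_frame(rng, n)
        F.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            exploratory_screen(rng.normal(size=n), F, None, n_perm=20)


class TestMdPc1:
    def test_single_tract(self, rng):
        x = rng.normal(size=30)
        out = md_pc1(x[:, None])
        assert out["variance_fraction"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(np.abs(out["scores"]), np.abs(z), atol=1e-10)

    def test_two_perfectly_correlated_tracts(self, rng):
        x = rng.normal(size=40)
        out = md_pc1(np.column_stack([x, 2 * x + 1]))
        assert out["variance_fraction"] == pytest.approx(1.0)

    def test_equicorrelation_top_eigenvalue(self):
        """k=5 tracts with rho = 0.8: PC1 fraction = (1 + 4*0.8)/5 = 0.84."""
        rng = np.random.default_rng(77)
        n, k, rho = 10000, 5, 0.8
        shared = rng.normal(size=n)
        M = (np.sqrt(rho) * shared[:, None]
             + np.sqrt(1 - rho) * rng.normal(size=(n, k)))
        out = md_pc1(M, standardize=True)
        assert out["variance_fraction"] == pytest.approx(0.84, abs=0.01)

    def test_sign_convention_mean_loading_positive(self, rng):
        M = rng.normal(size=(50, 4)) + rng.normal(size=(50, 1))
        out = md_pc1(M)
        assert out["loadings"].mean() > 0

    def test_variance_fractions_sum_to_one_and_pc1_maximal(self, rng):
        M = rng.normal(size=(30, 6))
        Mc = (M - M.mean(0)) / M.std(0, ddof=1)
        s = np.linalg.svd(Mc, compute_uv=False)
        fracs = s ** 2 / np.sum(s ** 2)
        assert fracs.sum() == pytest.approx(1.0)
        assert md_pc1(M)["variance_fraction"] == pytest.approx(fracs[0])

    def test_zero_variance_column_rejected(self, rng):
        M = np.column_stack([rng.normal(size=10), np.ones(10)])
        with pytest.raises(ValueError):
            md_pc1(M)


class TestConfirmatoryTest:
    def test_positive_r_under_negative_hypothesis_gives_large_p(self, rng):
        n = 20
        m = rng.normal(size=n)
        y = m + 0.2 * rng.normal(size=n)                # positive association
        M = pd.DataFrame({t: m + 0.3 * rng.normal(size=n)
                          for t in CONFIRMED_TRACTS})
        out = confirmatory_test(y, M, direction="negative", n_perm=500, seed=0)
        assert out["pc1_r"] > 0
        assert out["p"].p >= 0.5

    def test_incomplete_rows_dropped(self, rng):
        n = 18
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in CONFIRMED_TRACTS})
        M.iloc[3] = np.nan
        out = confirmatory_test(y, M, n_perm=100, seed=0)
        assert out["n"] == 17

    def test_polarity_signs_match_adjusted_correlations(self, rng):
        n = 25
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in CONFIRMED_TRACTS})
        Z = rng.normal(size=(n, 2))
        out = confirmatory_test(y, M, Z, n_perm=50, seed=0)
        for _, row in out["polarity"].iterrows():
            assert row["r"] == pytest.approx(
                adjusted_correlation(M[row["tract"]], y, Z), abs=1e-10)


class TestSubsetCombination:
    def test_three_tract_universe_enumerates_seven_subsets(self, rng):
        n = 30
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in ("a", "b", "c")})
        out = subset_combination_analysis(y, M, target_subset=("a", "b"))
        assert out["n_subsets"] == 7
        assert len(out["r2"]) == 7

    def test_maximal_subset_has_percentile_100(self, rng):
        n = 40
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in ("a", "b", "c", "d")})
        out = subset_combination_analysis(y, M, target_subset=("a",))
        best = int(out["r2"].loc[out["r2"]["r2"].idxmax(), "subset_bitmask"])
        tracts = [t for j, t in enumerate(out["tracts"]) if best >> j & 1]
        out_best = subset_combination_analysis(y, M, target_subset=tracts)
        assert out_best["percentile"] == pytest.approx(100.0)

    def test_matches_brute_force_pca_oracle(self, rng):
        """Every subset r^2 equals an explicit md_pc1 + adjusted_correlation
        recomputation on a 4-tract universe."""
        from neonoci.structfun import _residuals
        n = 35
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in ("a", "b", "c", "d")})
        Z = rng.normal(size=(n, 2))
        out = subset_combination_analysis(y, M, Z, target_subset=("a", "c"))
        cols = list(M.columns)
        for _, row in out["r2"].iterrows():
            s = int(row["subset_bitmask"])
            sub = [cols[j] for j in range(4) if s >> j & 1]
            basis = _residuals(M[sub].to_numpy(float), Z)
            pc1 = md_pc1(basis)["scores"]
            oracle = adjusted_correlation(pc1, y, Z) ** 2
            assert row["r2"] == pytest.approx(oracle, abs=1e-9)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_percentile_invariant_to_monotone_rescaling(self, scale):
        rng = np.random.default_rng(4)
        n = 25
        y = rng.normal(size=n)
        M = pd.DataFrame({t: rng.normal(size=n) for t in ("a", "b", "c")})
        base = subset_combination_analysis(y, M, target_subset=("a", "b"))
        scaled = subset_combination_analysis(scale * y, M, target_subset=("a", "b"))
        assert scaled["percentile"] == pytest.approx(base["percentile"])

    def test_empty_target_rejected(self, rng):
        M = pd.DataFrame({t: rng.normal(size=10) for t in ("a", "b")})
        with pytest.raises(ValueError):
            subset_combination_analysis(rng.normal(size=10), M, target_subset=())


class TestCompareProfiles:
    def test_identical_profiles(self, rng):
        r = rng.normal(size=16)
        assert compare_tract_profiles(r, r) == pytest.approx(1.0)

    def test_affine_anticorrelation(self, rng):
        r = rng.normal(size=16)
        assert compare_tract_profiles(r, -r + 0.3) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, rng):
        a, b = rng.normal(size=(2, 16))
        assert compare_tract_profiles(a, b) == pytest.approx(
            np.corrcoef(a, b)[0, 1])

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_tract_profiles(rng.normal(size=5), rng.normal(size=6))
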