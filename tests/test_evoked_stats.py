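"""Subject GLM, group map, amplitude and template-expression statistics."""

import numpy as np
import pandas as pd
import pytest

from neonoci.evoked import (
    build_design,
    effective_tests,
    glm_fit,
    group_expression_test,
    group_tmap,
    overall_amplitude,
    perm_correlation,
    template_expression,
)
from neonoci.images import Bold4D, VoxelMap

from conftest import random_map


def _make_bold(geometry, signal_vt, n_vols):
    data = np.zeros(geometry.grid_shape + (n_vols,))
    data[geometry.mask] = signal_vt
    return Bold4D(data, tr=1.3, mask=geometry.mask.copy())


class TestGlmFit:
    def test_noiseless_beta_recovered_exactly(self, geometry, events):
        X = build_design(events, 100, 1.3)
        V = int(geometry.mask.sum())
        sig = 5.0 + 2.0 * np.tile(X[:, 0], (V, 1))
        fit = glm_fit(_make_bold(geometry, sig, 100), X)
        assert np.allclose(fit.stimulus_beta.values(), 2.0, atol=1e-10)
        assert fit.df == 100 - X.shape[1]

    def test_matches_normal_equations_oracle(self, rng):
        """Random small instance vs the closed-form (X'X)^-1 X'y solution."""
        from neonoci.simulate import PhantomGeometry
        geo = PhantomGeometry((4, 4, 4))
        T = 30
        X = np.column_stack([rng.normal(size=T), np.ones(T), rng.normal(size=T)])
        V = int(geo.mask.sum())
        Y = rng.normal(size=(V, T))
        fit = glm_fit(_make_bold(geo, Y, T), X)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y.T)   # (p, V)
        for j, bmap in enumerate(fit.betas):
            assert np.allclose(bmap.values(), oracle[j], atol=1e-10)
        # R^2 map within [0, 1]
        assert np.all((fit.goodness_of_fit.values() >= 0)
                      & (fit.goodness_of_fit.values() <= 1))

    def test_duplicated_design_column_rejected(self, geometry, events):
        X = build_design(events, 100, 1.3)
        Xdup = np.column_stack([X, X[:, 0]])
        bold = _make_bold(geometry, np.zeros((int(geometry.mask.sum()), 100)), 100)
        with pytest.raises(ValueError, match="rank deficient"):
            glm_fit(bold, Xdup)

    def test_volume_count_mismatch_rejected(self, geometry, events):
        X = build_design(events, 100, 1.3)
        bold = _make_bold(geometry, np.zeros((int(geometry.mask.sum()), 99)), 99)
        with pytest.raises(ValueError):
            glm_fit(bold, X)


class TestGroupTmap:
    def test_hand_arithmetic(self, geometry):
        """Across-subject values {1, 2, 3}: t = 2 / (1/sqrt(3)) = 2 sqrt(3)."""
        maps = [geometry.blank().with_data(np.full(geometry.grid_shape, v))
                for v in (1.0, 2.0, 3.0)]
        t = group_tmap(maps)
        assert np.allclose(t.values(), 2.0 * np.sqrt(3.0), atol=1e-12)

    def test_zero_variance_gives_zero_with_warning(self, geometry):
        maps = [geometry.blank() for _ in range(3)]
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t = group_tmap(maps)
        assert np.all(t.values() == 0.0)

    def test_antisymmetry(self, geometry, rng):
        maps = [random_map(rng, geometry) for _ in range(5)]
        neg = [m.with_data(-m.data) for m in maps]
        assert np.allclose(group_tmap(neg).values(), -group_tmap(maps).values())

    def test_single_map_rejected(self, geometry, rng):
        with pytest.raises(ValueError):
            group_tmap([random_map(rng, geometry)])


class TestOverallAmplitude:
    def test_affine_subject_map_gives_exact_slope(self, group_map):
        subject = group_map.with_data(3.0 * group_map.data + 7.0)
        assert overall_amplitude(subject, group_map) == pytest.approx(3.0, abs=1e-12)

    def test_matches_covariance_oracle(self, geometry, rng):
        for _ in range(20):
            g, s = random_map(rng, geometry), random_map(rng, geometry)
            gv, sv = g.values(), s.values()
            oracle = np.cov(gv, sv)[0, 1] / np.var(gv, ddof=1)
            assert overall_amplitude(s, g) == pytest.approx(oracle, abs=1e-10)

    def test_orthogonal_map_gives_zero(self, geometry, rng):
        g = random_map(rng, geometry)
        gv = g.data[g.mask] - g.data[g.mask].mean()
        s = random_map(rng, geometry)
        sv = s.data[s.mask]
        sv = sv - np.dot(sv, gv) / np.dot(gv, gv) * gv
        assert overall_amplitude(g.embed(sv), g) == pytest.approx(0.0, abs=1e-10)

    def test_affine_equivariance(self, geometry, rng):
        g, s = random_map(rng, geometry), random_map(rng, geometry)
        base = overall_amplitude(s, g)
        scaled = overall_amplitude(s.with_data(2.5 * s.data - 4.0), g)
        assert scaled == pytest.approx(2.5 * base, rel=1e-10)

    def test_constant_group_map_rejected(self, geometry, rng):
        flat = geometry.blank().with_data(np.ones(geometry.grid_shape))
        with pytest.raises(ValueError):
            overall_amplitude(random_map(rng, geometry), flat)


class TestTemplateExpression:
    def test_self_expression_is_one(self, group_map):
        assert template_expression(group_map, group_map) == pytest.approx(1.0)
        assert template_expression(group_map, group_map,
                                   method="cosine") == pytest.approx(1.0)

    def test_four_voxel_hand_case(self):
        """map (1,2,3,4) vs template (1,0,0,1): covariance is zero."""
        m = VoxelMap(np.array([1.0, 2, 3, 4]).reshape(4, 1, 1))
        t = VoxelMap(np.array([1.0, 0, 0, 1]).reshape(4, 1, 1))
        assert template_expression(m, t) == pytest.approx(0.0, abs=1e-12)

    def test_cosine_of_orthogonal_maps_is_zero(self):
        m = VoxelMap(np.array([1.0, 0, 1, 0]).reshape(4, 1, 1))
        t = VoxelMap(np.array([0.0, 1, 0, 1]).reshape(4, 1, 1))
        assert template_expression(m, t, method="cosine") == 0.0

    def test_constant_map_rejected_for_pearson(self, group_map):
        flat = group_map.with_data(np.ones(group_map.shape))
        with pytest.raises(ValueError):
            template_expression(flat, group_map)


class TestGroupExpressionTest:
    def test_exhaustive_enumeration_small_case(self):
        """{1,2,3}: only the two all-same-sign patterns reach |t|=2 sqrt(3),
        so the two-tailed exhaustive p is 2/8."""
        res = group_expression_test([1.0, 2.0, 3.0])
        assert res.convention == "exhaustive"
        assert res.n_perm == 8
        assert res.p == pytest.approx(0.25)
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0))

    def test_balanced_pair_gives_p_one(self):
        res = group_expression_test([-1.0, 1.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_minimum_attainable_p(self, rng):
        for n in (3, 4, 5):
            x = rng.normal(size=n) + 50.0   # overwhelming effect
            res = group_expression_test(list(x))
            assert res.p >= 2.0 / 2 ** n - 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            group_expression_test([2.0, 2.0, 2.0])


class TestPermCorrelation:
    def test_exhaustive_identical_orderings(self):
        """x = y = (1,2,3), one-tailed positive: only the identity ordering
        reaches r = 1, so p = 1/6."""
        res = perm_correlation([1, 2, 3], [1, 2, 3], tails="one",
                               direction="positive")
        assert res.convention == "exhaustive"
        assert res.p == pytest.approx(1.0 / 6.0)
        assert res.statistic == pytest.approx(1.0)

    def test_joint_permutation_invariance(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        r1 = perm_correlation(x, y, n_perm=50).statistic
        r2 = perm_correlation(x[perm], y[perm], n_perm=50).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self):
        x = np.array([0.3, -1.2, 0.8, 1.9, -0.4, 0.6])
        y = np.array([1.1, 0.2, -0.7, 1.4, 0.9, -0.2])
        ex = perm_correlation(x, y, n_perm=720)       # 6! = 720 -> exhaustive
        assert ex.convention == "exhaustive"
        B = 600                                       # < 720 -> Monte-Carlo
        mc = perm_correlation(x, y, n_perm=B, seed=5)
        assert mc.convention == "monte_carlo"
        # agreement within 3 binomial SEs
        se = np.sqrt(ex.p * (1 - ex.p) / B)
        assert abs(mc.p - ex.p) < 3 * se + 2.0 / B

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            perm_correlation([1, 1, 1], [1, 2, 3])


class TestEffectiveTests:
    def test_identity_matrix(self):
        for method in ("liji", "nyholt"):
            out = effective_tests(np.eye(10), method=method)
            assert out["m_eff"] == pytest.approx(10.0)

    def test_all_ones_matrix(self):
        for method in ("liji", "nyholt"):
            out = effective_tests(np.ones((6, 6)), method=method)
            assert out["m_eff"] == pytest.approx(1.0, abs=1e-9)

    def test_two_variable_hand_eigenvalues(self):
        """r = 0.6: eigenvalues {1.6, 0.4}, var = 0.72,
        m_eff = 1 + 1*(1 - 0.72/2) = 1.64."""
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = effective_tests(C, method="nyholt")
        assert out["m_eff"] == pytest.approx(1.64)

    def test_corrected_alpha_printed_precision(self):
        # alpha 0.05 over an effective count of 8.3403 -> 0.0060 at 4 dp
        assert 0.05 / 8.3403 == pytest.approx(0.0060, abs=5e-5)
        out = effective_tests(np.eye(3))
        assert out["corrected_alpha"] == pytest.approx(0.05 / 3)

    def test_asymmetric_matrix_rejected(self):
        C = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            effective_tests(C)
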