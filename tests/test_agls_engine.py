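import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from episcan import (AdjustedTrait, DegenerateFitError, TraitRecords,
                     adjust_phenotype, contrast_coefficients, extreme_log10p,
                     fit_pair, test_contrast)
from episcan.agls_engine import EFFECT_TYPES, contrast_tests_block, pair_block_stats

import oracle


class TestAdjustPhenotype:
    def test_definition(self):
        rec = TraitRecords(["a", "b"], np.array([10.0, 0.0]),
                           np.array([2.0, 0.0]), "t")
        np.testing.assert_array_equal(adjust_phenotype(rec).y_adj, [6.0, 0.0])

    def test_matches_elementwise_loop(self, rng):
        y = rng.normal(size=50)
        pta = rng.normal(size=50)
        rec = TraitRecords([f"i{k}" for k in range(50)], y, pta, "t")
        got = adjust_phenotype(rec).y_adj
        for k in range(50):
            assert got[k] == y[k] - 2 * pta[k]


class TestContrastCoefficients:
    def test_aa_pattern(self):
        s = contrast_coefficients("AA").reshape(3, 3)
        assert s[0, 0] == s[2, 2] == 1
        assert s[0, 2] == s[2, 0] == -1
        assert np.count_nonzero(s) == 4

    def test_dd_pattern(self):
        s = contrast_coefficients("DD").reshape(3, 3)
        assert s[1, 1] == 1.0
        for cell in ((0, 1), (2, 1), (1, 0), (1, 2)):
            assert s[cell] == -0.5
        for cell in ((0, 0), (0, 2), (2, 0), (2, 2)):
            assert s[cell] == 0.25

    def test_zero_sum_and_mutual_orthogonality(self):
        vecs = [contrast_coefficients(et) for et in EFFECT_TYPES]
        for v in vecs:
            assert v.sum() == pytest.approx(0.0)
        for i in range(4):
            for j in range(i + 1, 4):
                assert vecs[i] @ vecs[j] == pytest.approx(0.0)

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            contrast_coefficients("AB")


def balanced_design(values_by_cell):
    """Two observations per 3x3 cell with symmetric +-d noise around means."""
    g1, g2, y = [], [], []
    for j in range(3):
        for k in range(3):
            mu = values_by_cell[j][k]
            for d in (-0.5, 0.5):
                g1.append(j)
                g2.append(k)
                y.append(mu + d)
    return (np.array(y), np.array(g1, dtype=np.int8),
            np.array(g2, dtype=np.int8))


class TestFitPair:
    def test_constant_response(self):
        y, g1, g2 = balanced_design([[3.0] * 3] * 3)
        y[:] = 3.0
        fit = fit_pair(y, g1, g2)
        np.testing.assert_allclose(fit.cell_means, 3.0)
        assert fit.v2 == 0.0

    def test_hand_computed_cell_means(self):
        cells = [[0.0, 1.0, 2.0], [3.0, 4.0, 5.0], [6.0, 7.0, 8.0]]
        y, g1, g2 = balanced_design(cells)
        fit = fit_pair(y, g1, g2)
        np.testing.assert_allclose(fit.cell_means, cells)
        assert fit.df == 18 - 9
        assert fit.n_used == 18
        # two obs at +-0.5 around each mean: RSS = 9 cells * 0.5 -> v2 = 0.5
        assert fit.v2 == pytest.approx(0.5)
        np.testing.assert_allclose(fit.xtx_inv_gg, 0.5)

    def test_missing_genotypes_pairwise_complete(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g1 = np.array([0, 0, 1, 1, -1, 0], dtype=np.int8)
        g2 = np.array([0, 0, 1, 1, 1, -1], dtype=np.int8)
        fit = fit_pair(y, g1, g2)
        assert fit.n_used == 4
        assert fit.cell_counts[0, 0] == 2 and fit.cell_counts[1, 1] == 2

    def test_degenerate_raises(self):
        y = np.array([1.0, 2.0])
        g = np.array([0, 1], dtype=np.int8)
        with pytest.raises(DegenerateFitError):
            fit_pair(y, g, g)

    def test_matches_ls_oracle(self, rng):
        for _ in range(20):
            y, g1, g2 = oracle.random_instance(rng, n=60)
            try:
                fit = fit_pair(y, g1, g2)
            except DegenerateFitError:
                continue
            beta, xtx_inv, v2, df, occupied = oracle.ls_fit(y, g1, g2)
            np.testing.assert_allclose(fit.ghat, beta, rtol=1e-10)
            assert fit.v2 == pytest.approx(v2, rel=1e-10)
            assert fit.df == df


class TestTestContrast:
    def test_equal_cell_means_null(self):
        y, g1, g2 = balanced_design([[2.0] * 3] * 3)
        fit = fit_pair(y, g1, g2)
        for et in EFFECT_TYPES:
            r = test_contrast(fit, et)
            assert r.estimable
            assert r.L == pytest.approx(0.0, abs=1e-12)
            assert r.t == pytest.approx(0.0, abs=1e-12)
            assert r.p == pytest.approx(1.0)

    def test_additive_surface_annihilated(self):
        a, b = 1.3, -0.7
        cells = [[a * j + b * k for k in range(3)] for j in range(3)]
        y, g1, g2 = balanced_design(cells)
        fit = fit_pair(y, g1, g2)
        for et in EFFECT_TYPES:
            r = test_contrast(fit, et)
            assert r.L == pytest.approx(0.0, abs=1e-12)

    def test_empty_weighted_cell_not_estimable(self):
        # remove the (2,2) cell: AA needs it, DD needs it too; AD needs (2,*)
        y, g1, g2 = balanced_design([[0.0] * 3] * 3)
        keep = ~((g1 == 2) & (g2 == 2))
        fit = fit_pair(y[keep], g1[keep], g2[keep])
        assert not test_contrast(fit, "AA").estimable
        assert not test_contrast(fit, "DD").estimable

    def test_zero_variance_flagged_not_raised(self):
        # y exactly equal to its cell mean everywhere: v2 = 0 so var(L) = 0
        cells = [[1.0, 0.0, 0.0], [0.0] * 3, [0.0] * 3]
        g1 = np.repeat(np.arange(3, dtype=np.int8), 6)
        g2 = np.tile(np.repeat(np.arange(3, dtype=np.int8), 2), 3)
        y = np.array([cells[a][b] for a, b in zip(g1, g2)], dtype=float)
        fit = fit_pair(y, g1, g2)
        r = test_contrast(fit, "AA")
        assert not r.estimable

    def test_matches_ls_oracle(self, rng):
        checked = 0
        while checked < 30:
            y, g1, g2 = oracle.random_instance(rng, n=80)
            try:
                fit = fit_pair(y, g1, g2)
            except DegenerateFitError:
                continue
            for et in EFFECT_TYPES:
                expected = oracle.ls_contrast(y, g1, g2, et)
                got = test_contrast(fit, et)
                if expected is None:
                    assert not got.estimable
                    continue
                L, var_L, t, p, df = expected
                assert got.L == pytest.approx(L, rel=1e-10, abs=1e-12)
                assert got.var_L == pytest.approx(var_L, rel=1e-10)
                assert got.t == pytest.approx(t, rel=1e-10, abs=1e-12)
                assert got.p == pytest.approx(p, rel=1e-8)
            checked += 1


class TestExtremeLog10P:
    def test_t_zero(self):
        assert extreme_log10p(0.0, 100) == pytest.approx(0.0)

    def test_boundary_agreement(self):
        # at the underflow boundary (t ~ 37.6, large df) the power-law branch
        # agrees with the exact normal-tail log10(1/p) ~ 308 within 2%
        from scipy import stats
        t = 37.6
        exact = -(stats.norm.logsf(t) + np.log(2)) / np.log(10)
        formula = 0.2416 * t**1.9713
        assert formula == pytest.approx(exact, rel=0.02)
        assert exact == pytest.approx(308, rel=0.01)

    @pytest.mark.parametrize("df", [100, 5000, 10**6])
    def test_monotone_on_grid(self, df):
        grid = np.linspace(0.0, 200.0, 2001)
        vals = extreme_log10p(grid, df)
        assert np.all(np.diff(vals) >= -1e-9)

    def test_consistent_with_p_when_representable(self):
        from scipy import stats
        t, df = 5.0, 50
        assert extreme_log10p(t, df) == pytest.approx(
            -np.log10(2 * stats.t.sf(t, df)))

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            extreme_log10p(-1.0, 10)


class TestSymmetries:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        y, g1, g2 = oracle.random_instance(rng, n=100, maf_range=(0.2, 0.5))
        try:
            fit = fit_pair(y, g1, g2)
            fit_flipped = fit_pair(y, 2 - g1, g2)
        except DegenerateFitError:
            return
        for et in EFFECT_TYPES:
            r = test_contrast(fit, et)
            rf = test_contrast(fit_flipped, et)
            assert r.estimable == rf.estimable
            if not r.estimable:
                continue
            assert rf.t == pytest.approx(r.t, rel=1e-10, abs=1e-12)
            assert rf.p == pytest.approx(r.p, rel=1e-8)
            sign = -1.0 if et[0] == "A" else 1.0  # A factor at SNP1 flips L
            assert rf.L == pytest.approx(sign * r.L, rel=1e-10, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_pair_order_swap(self, seed):
        rng = np.random.default_rng(seed)
        y, g1, g2 = oracle.random_instance(rng, n=100, maf_range=(0.2, 0.5))
        try:
            f12 = fit_pair(y, g1, g2)
            f21 = fit_pair(y, g2, g1)
        except DegenerateFitError:
            return
        for et, swapped in (("AD", "DA"), ("DA", "AD"), ("AA", "AA"), ("DD", "DD")):
            r = test_contrast(f12, et)
            rs = test_contrast(f21, swapped)
            assert r.estimable == rs.estimable
            if r.estimable:
                assert rs.L == pytest.approx(r.L, rel=1e-10, abs=1e-12)
                assert rs.t == pytest.approx(r.t, rel=1e-10, abs=1e-12)
                assert rs.p == pytest.approx(r.p, rel=1e-8)

    def test_contrast_scale_invariance(self, rng):
        # scaling the contrast vector by c rescales L and var(L) so t is fixed
        y, g1, g2 = oracle.random_instance(rng, n=120, maf_range=(0.25, 0.5))
        fit = fit_pair(y, g1, g2)
        for et in EFFECT_TYPES:
            s = contrast_coefficients(et)[fit.occupied]
            for c in (0.5, -3.0, 7.25):
                L = c * s @ fit.ghat
                var_L = fit.v2 * (c * s) ** 2 @ fit.xtx_inv_gg
                t_scaled = abs(L) / np.sqrt(var_L)
                base = test_contrast(fit, et)
                if base.estimable:
                    assert t_scaled == pytest.approx(base.t, rel=1e-10)


class TestBlockKernels:
    def test_block_matches_scalar_path(self, rng):
        n, m = 150, 12
        G = rng.binomial(2, 0.35, size=(n, m)).astype(np.int8)
        G[rng.random(size=(n, m)) < 0.03] = -1
        y = rng.standard_normal(n)
        counts, ysum, ysq = pair_block_stats(G[:, 0], G[:, 1:], y)
        res = contrast_tests_block(counts, ysum, ysq)
        for j in range(m - 1):
            try:
                fit = fit_pair(y, G[:, 0], G[:, j + 1])
            except DegenerateFitError:
                assert res["degenerate"][j]
                continue
            for ti, et in enumerate(EFFECT_TYPES):
                r = test_contrast(fit, et)
                assert res["estimable"][j, ti] == r.estimable
                if r.estimable:
                    assert res["t"][j, ti] == pytest.approx(r.t, rel=1e-12)
                    assert res["p"][j, ti] == pytest.approx(r.p, rel=1e-10)
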