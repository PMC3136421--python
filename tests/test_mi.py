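"""Copula transform, Gaussian MI estimator, permutation null, p-values, MTC."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from grnilab import (
    ExpressionMatrix,
    adjust_pvalues,
    build_null,
    copula_transform,
    mi_gaussian,
    mi_matrix,
    mi_pvalues,
    significance_mask,
)


def expr(vals, genes=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(vals.shape[0])]
    return ExpressionMatrix(genes, [f"S{i + 1}" for i in range(vals.shape[1])], vals)


class TestCopulaTransform:
    def test_rank_scaling(self):
        out = copula_transform(np.array([[3.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out[0], [0.75, 0.25, 0.50])

    def test_ties_average(self):
        out = copula_transform(np.array([[5.0, 5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out[0], [0.5] * 4)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random((3, 40))
        np.testing.assert_array_equal(copula_transform(x), copula_transform(np.exp(x)))

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            copula_transform(np.array([[1.0]]))


class TestMiGaussian:
    def test_independence_limit(self):
        # under independence the estimate concentrates near zero
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            hits += mi_gaussian(rng.random(10_000), rng.random(10_000)) < 0.01
        assert hits >= 0.95 * 40

    def test_closed_form_convergence(self):
        # copula-scale correlation rho=0.5 -> -0.5*ln(0.75) ~ 0.1438 nats.
        # A Gaussian pair with latent correlation 2*sin(pi/12) has Spearman
        # (hence copula-scale Pearson) correlation exactly 0.5.
        rng = np.random.default_rng(1)
        latent = 2 * np.sin(np.pi / 12)
        cov = [[1.0, latent], [latent, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=100_000).T
        expected = -0.5 * np.log(0.75)
        assert abs(mi_gaussian(xy[0], xy[1]) - expected) < 0.01

    def test_sign_flip_and_monotone_maximal(self):
        rng = np.random.default_rng(2)
        x = rng.random(200)
        assert mi_gaussian(x, -x) == pytest.approx(mi_gaussian(x, np.exp(x)))
        assert mi_gaussian(x, -x) > 10  # clipped near-perfect dependence

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mi_gaussian(np.ones(3), np.ones(4))


class TestMiMatrix:
    def test_two_gene_symmetry(self):
        rng = np.random.default_rng(3)
        m = mi_matrix(expr(rng.random((2, 30)))).values
        assert m[0, 1] == m[1, 0] > 0 and m[0, 0] == m[1, 1] == 0

    def test_duplicated_gene_maximal(self):
        rng = np.random.default_rng(4)
        x = rng.random(50)
        m = mi_matrix(expr(np.vstack([x, x, rng.random(50)]))).values
        assert m[0, 1] == m.max() > 10

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(5)
        vals = rng.random((5, 60))
        m = mi_matrix(expr(vals)).values
        for i in range(5):
            for j in range(i + 1, 5):
                assert m[i, j] == pytest.approx(mi_gaussian(vals[i], vals[j]), abs=1e-12)


class TestNullModel:
    def test_pool_size_and_determinism(self):
        data = expr(np.random.default_rng(0).random((3, 20)))
        null = build_null(data, itnum=1, seed=1)
        assert null.null_values.size == 3  # n(n-1)/2 pairs per iteration
        null2 = build_null(data, itnum=1, seed=1)
        np.testing.assert_array_equal(null.null_values, null2.null_values)

    def test_null_matches_observed_under_independence(self):
        # on independent data the permutation null holds by construction
        hits = 0
        for s in range(20):
            data = expr(np.random.default_rng(s).random((10, 30)))
            null = build_null(data, itnum=3, seed=s + 100)
            observed = mi_matrix(data).values[np.triu_indices(10, k=1)]
            _, p = ks_2samp(observed, null.null_values)
            hits += p > 0.01
        assert hits >= 0.9 * 20


class TestPValues:
    def test_add_one_rule_extremes(self):
        from grnilab import MIMatrix, NullModel

        null = NullModel(np.linspace(0.001, 0.05, 99), itnum=1, seed=0)
        mim = MIMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        p = mi_pvalues(mim, null)
        assert p[0, 1] == pytest.approx(1 / 100)
        low = MIMatrix(["A", "B"], np.array([[0.0, 1e-9], [1e-9, 0.0]]))
        assert mi_pvalues(low, null)[0, 1] == 1.0

    def test_hand_counted(self):
        from grnilab import MIMatrix, NullModel

        null = NullModel(np.array([0.1, 0.2, 0.3, 0.4]), itnum=1, seed=0)
        mim = MIMatrix(["A", "B"], np.array([[0.0, 0.25], [0.25, 0.0]]))
        assert mi_pvalues(mim, null)[0, 1] == pytest.approx((1 + 2) / 5)


class TestAdjustPvalues:
    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02], "bonferroni"), [0.02, 0.04]
        )

    def test_bh_step_up(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH"), [0.04] * 4
        )

    @pytest.mark.parametrize("method", ["BH", "bonferroni", "BY", "hochberg", "holm"])
    def test_single_p_unchanged(self, method):
        np.testing.assert_allclose(adjust_pvalues([0.03], method), [0.03])

    def test_dominance_ordering(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        bonf = adjust_pvalues(p, "bonferroni")
        holm = adjust_pvalues(p, "holm")
        bh = adjust_pvalues(p, "BH")
        assert np.all(bonf >= holm - 1e-12) and np.all(holm >= bh - 1e-12)
        for method in ["BH", "bonferroni", "BY", "hochberg", "holm"]:
            assert np.all(adjust_pvalues(p, method) >= p - 1e-12)

    def test_hommel_alias_warns(self):
        with pytest.warns(UserWarning, match="hochberg"):
            out = adjust_pvalues([0.01, 0.5], "hommel")
        np.testing.assert_allclose(out, adjust_pvalues([0.01, 0.5], "hochberg"))

    def test_unknown_method_lists_options(self):
        with pytest.raises(ValueError, match="BH"):
            adjust_pvalues([0.5], "fdr_magic")


class TestSignificanceMask:
    def test_cutoff_extremes(self):
        rng = np.random.default_rng(7)
        mim = mi_matrix(expr(rng.random((4, 30))))
        all_false = significance_mask(mim, "cutoff", cutoff_mi=mim.values.max() + 1)
        assert not all_false.mask.any()
        all_true = significance_mask(mim, "cutoff", cutoff_mi=0.0)
        off_diag = ~np.eye(4, dtype=bool)
        assert all_true.mask[off_diag].all()

    def test_justp_counts(self):
        data = expr(np.random.default_rng(8).random((6, 25)))
        mim = mi_matrix(data)
        mask = significance_mask(mim, "justp", alpha=0.05, itnum=4, seed=9, data=data)
        null = build_null(data, 4, 9)
        p = mi_pvalues(mim, null)
        iu = np.triu_indices(6, k=1)
        assert mask.mask[iu].sum() == (p[iu] < 0.05).sum()

    def test_missing_dependent_parameters_named(self):
        mim = mi_matrix(expr(np.random.default_rng(0).random((3, 10))))
        with pytest.raises(ValueError, match="'data'"):
            significance_mask(mim, "justp", seed=1)
        with pytest.raises(ValueError, match="'seed'"):
            significance_mask(mim, "MTC", data=expr(np.ones((3, 10)) + np.arange(30).reshape(3, 10)))
        with pytest.raises(ValueError, match="'mtc_method'"):
            data = expr(np.random.default_rng(0).random((3, 10)))
            significance_mask(mim, "MTC", data=data, seed=1, mtc_method=None)
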