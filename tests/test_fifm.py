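"""The sum-of-single-effects fitter, credible sets, purity, and reweighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emscore import fifm, synthdata


def single_effect_oracle(X, y, prior_variance, sigma2):
    """Exhaustive single-causal Bayes computation on standardized genotypes."""
    n, m = X.shape
    Z = (X - X.mean(0)) / X.std(0)
    yc = y - y.mean()
    Xty = Z.T @ yc
    xtx = np.full(m, float(n))
    s2 = sigma2 / xtx
    betahat = Xty / xtx
    log_bf = 0.5 * np.log(s2 / (s2 + prior_variance)) \
        + 0.5 * betahat**2 / s2 * prior_variance / (prior_variance + s2)
    a = np.exp(log_bf - log_bf.max())
    return a / a.sum()


class TestIbssFit:
    def test_single_effect_matches_exhaustive_bayes_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(20, 60))
            m = int(rng.integers(3, 12))
            X = rng.normal(size=(n, m))
            y = rng.normal(size=n) + 0.4 * X[:, int(rng.integers(m))]
            fit = fifm.ibss_fit(X, y, L=1,
                                estimate_prior_variance=False, prior_variance=0.2,
                                estimate_residual_variance=False, residual_variance=1.0)
            expected = single_effect_oracle(X, y, 0.2, 1.0)
            np.testing.assert_allclose(fit.alphas[0], expected, atol=1e-6)

    def test_strong_causal_variant_reaches_high_pip(self):
        hits = 0
        for seed in range(20):
            G = synthdata.simulate_ld_genotypes(500, [10] * 3, rho=0.5, seed=seed)
            locus = synthdata.SyntheticLocus(G, [10] * 3, 0.5)
            synthdata.simulate_expression(
                locus, 1, noise_sd=0.5, seed=seed,
                causal_indices=np.array([7]), effects=np.array([1.5]))
            fit = fifm.ibss_fit(G, locus.expression, L=3)
            hits += fifm.compute_pip(fit)[7] > 0.95
        assert hits >= 18

    def test_pure_noise_rarely_yields_a_pure_credible_set(self):
        clean = 0
        for seed in range(10):
            G = synthdata.simulate_ld_genotypes(300, [10] * 3, rho=0.5, seed=seed)
            y = np.random.default_rng(1000 + seed).normal(size=300)
            fit = fifm.ibss_fit(G, y, L=3)
            sets = fifm.credible_sets(fit, np.corrcoef(G, rowvar=False))
            clean += not any(cs.pure for cs in sets)
        assert clean >= 9

    def test_constant_phenotype_rejected(self):
        G = np.random.default_rng(2).normal(size=(20, 5))
        with pytest.raises(ValueError):
            fifm.ibss_fit(G, np.ones(20), L=1)

    def test_alpha_rows_are_probability_vectors(self):
        G = synthdata.simulate_ld_genotypes(100, [5, 5], rho=0.3, seed=3)
        y = np.random.default_rng(3).normal(size=100)
        fit = fifm.ibss_fit(G, y, L=4)
        np.testing.assert_allclose(fit.alphas.sum(axis=1), 1.0, atol=1e-8)
        assert (fit.alphas >= 0).all()


class TestPip:
    def test_single_effect_pip_equals_alpha(self):
        a = np.array([[0.7, 0.2, 0.1]])
        np.testing.assert_allclose(fifm.compute_pip(a), a[0], atol=1e-15)

    def test_two_effect_product_formula(self):
        a = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        np.testing.assert_allclose(fifm.compute_pip(a), [0.75, 0.5, 0.5])

    def test_zero_alpha_gives_zero_pip(self):
        a = np.array([[0.5, 0.5, 0.0], [0.6, 0.4, 0.0]])
        assert fifm.compute_pip(a)[2] == 0.0


class TestCredibleSets:
    def test_point_mass_yields_singleton(self):
        assert fifm.credible_set_95(np.array([1.0, 0.0, 0.0])) == [0]

    def test_cumulative_prefix_rule(self):
        members = fifm.credible_set_95(np.array([0.5, 0.3, 0.15, 0.05]))
        assert members == [0, 1, 2]

    def test_perfect_ld_block_keeps_all_four(self):
        members = fifm.credible_set_95(np.array([0.25, 0.25, 0.25, 0.25]))
        assert len(members) == 4

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            fifm.credible_set_95(np.array([1.0]), coverage=0.0)


class TestPurity:
    def test_singleton_is_pure_with_unit_correlation(self):
        min_abs, pure = fifm.purity([2], np.eye(4))
        assert (min_abs, pure) == (1.0, True)

    def test_weakly_correlated_pair_is_impure(self):
        corr = np.array([[1.0, 0.4], [0.4, 1.0]])
        min_abs, pure = fifm.purity([0, 1], corr)
        assert min_abs == pytest.approx(0.4)
        assert not pure

    def test_perfect_ld_is_pure(self):
        min_abs, pure = fifm.purity([0, 1, 2, 3], np.ones((4, 4)))
        assert (min_abs, pure) == (1.0, True)

    def test_member_outside_matrix_rejected(self):
        with pytest.raises(ValueError):
            fifm.purity([0, 9], np.eye(3))


class TestReweighting:
    def test_published_worked_example(self):
        alphas = fifm.AlphaMatrix(np.full((1, 4), 0.25), list("abcd"))
        w = np.array([1.73e-3, 6.11e-5, 1.00e-5, 8.62e-6])
        out = fifm.reweight_alpha(alphas, w, [True])
        np.testing.assert_allclose(out.alphas[0],
                                   [0.956, 0.0338, 0.0055, 0.0048], atol=5e-4)

    def test_equal_weights_are_identity(self):
        rng = np.random.default_rng(4)
        a = rng.dirichlet(np.ones(6), size=3)
        alphas = fifm.AlphaMatrix(a, [f"v{i}" for i in range(6)])
        out = fifm.reweight_alpha(alphas, np.full(6, 0.37), [True] * 3)
        np.testing.assert_allclose(out.alphas, a, atol=1e-12)

    def test_direct_equation_evaluation(self):
        alphas = fifm.AlphaMatrix(np.array([[0.6, 0.4]]), ["a", "b"])
        out = fifm.reweight_alpha(alphas, np.array([1.0, 3.0]), [True])
        np.testing.assert_allclose(out.alphas[0], [1 / 3, 2 / 3])

    def test_impure_rows_untouched(self):
        a = np.array([[0.6, 0.4], [0.5, 0.5]])
        alphas = fifm.AlphaMatrix(a, ["a", "b"])
        out = fifm.reweight_alpha(alphas, np.array([1.0, 9.0]), [False, True])
        np.testing.assert_array_equal(out.alphas[0], a[0])
        assert not np.array_equal(out.alphas[1], a[1])

    def test_random_rows_sum_to_one_and_argmax_never_loses(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(2, 12))
            a = rng.dirichlet(np.ones(m))
            w = rng.lognormal(0, 2, size=m)
            alphas = fifm.AlphaMatrix(a[None, :], [f"v{i}" for i in range(m)])
            out = fifm.reweight_alpha(alphas, w, [True]).alphas[0]
            assert abs(out.sum() - 1.0) <= 1e-10
            j = int(np.argmax(w))
            assert out[j] >= a[j] - 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance_of_weights(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(5))
        w = rng.lognormal(0, 2, size=5)
        alphas = fifm.AlphaMatrix(a[None, :], [f"v{i}" for i in range(5)])
        out1 = fifm.reweight_alpha(alphas, w, [True]).alphas
        out2 = fifm.reweight_alpha(alphas, w * scale, [True]).alphas
        np.testing.assert_allclose(out1, out2, rtol=1e-9)

    def test_reweighting_then_uniform_is_noop(self):
        rng = np.random.default_rng(6)
        a = rng.dirichlet(np.ones(6))
        alphas = fifm.AlphaMatrix(a[None, :], [f"v{i}" for i in range(6)])
        once = fifm.reweight_alpha(alphas, rng.lognormal(0, 1, 6), [True])
        again = fifm.reweight_alpha(once, np.ones(6), [True])
        np.testing.assert_allclose(once.alphas, again.alphas, atol=1e-12)

    def test_zero_weighted_mass_left_unchanged_and_flagged(self):
        alphas = fifm.AlphaMatrix(np.array([[0.5, 0.5, 0.0]]), ["a", "b", "c"])
        out = fifm.reweight_alpha(alphas, np.array([0.0, 0.0, 5.0]), [True])
        np.testing.assert_array_equal(out.alphas, alphas.alphas)
        assert out.degenerate_rows == [0]


class TestFunctionallyInformedPips:
    def test_equal_weights_reproduce_uniform_pips(self):
        G = synthdata.simulate_ld_genotypes(200, [8, 8], rho=0.6, seed=7)
        locus = synthdata.SyntheticLocus(G, [8, 8], 0.6)
        synthdata.simulate_expression(locus, 1, beta_sd=1.0, seed=7)
        res = fifm.functionally_informed_pips(G, locus.expression,
                                              np.ones(16), L=3)
        np.testing.assert_allclose(res.pip_ems, res.pip_unif, atol=1e-12)

    def test_weight_dict_fills_missing_variants(self):
        G = synthdata.simulate_ld_genotypes(150, [6], rho=0.3, seed=8)
        locus = synthdata.SyntheticLocus(G, [6], 0.3)
        synthdata.simulate_expression(locus, 1, beta_sd=1.0, seed=8)
        ids = [f"v{j}" for j in range(6)]
        weights = {"v0": 0.9, "v1": 0.1}  # four variants unscored
        res = fifm.functionally_informed_pips(G, locus.expression, weights,
                                              L=2, variant_ids=ids)
        assert res.pip_ems.shape == (6,)
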