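"""Bayesian hierarchical model: conjugate updates, truncated-Gamma draws,
full fits against deterministic grid-integration oracles, and R-hat."""

import numpy as np
import pytest
from scipy import integrate, stats

import methylquant as mq
from methylquant.bayes import (BayesConfig, conditional_lambda_params,
                               fit_bayes_region, gelman_rubin, sample_phi)


def grid_posterior_mu_mean(x, y, c=1.0, a0=0.001, b0=0.001, n=40001):
    """Oracle: posterior mean of mu in Poisson mode by 1-D quadrature.

    The per-site depths integrate out analytically against their Gamma
    prior, leaving p(mu | x, y) proportional to
    prod_i (1-mu)^{y_i} / (1 + c(1-mu) + b0)^{x_i + y_i + a0} on (0,1).
    """
    mu = np.linspace(1e-9, 1 - 1e-9, n)
    logp = np.zeros_like(mu)
    for xi, yi in zip(x, y):
        logp += yi * np.log1p(-mu) + yi * np.log(c) \
            - (xi + yi + a0) * np.log(1 + c * (1 - mu) + b0)
    logp -= logp.max()
    w = np.exp(logp)
    return np.trapezoid(w * mu, mu) / np.trapezoid(w, mu)


def batch_means_mcse(summary, batch: int = 25) -> float:
    """Monte-Carlo standard error of mu_mean, batch means across chains."""
    draws = summary.mu_samples
    n_batches = draws.size // batch
    means = draws[:n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestConditionalLambdaParams:
    @pytest.mark.parametrize("x, y, mu, shape, rate", [
        (10, 0, 1.0, 10.001, 1.001),   # thinning term vanishes at mu = 1
        (5, 5, 0.0, 10.001, 2.001),
    ])
    def test_conjugate_algebra(self, x, y, mu, shape, rate):
        got = conditional_lambda_params(x, y, mu, 1.0, 0.001, 0.001)
        assert got == (pytest.approx(shape), pytest.approx(rate))

    def test_rejects_mu_outside_unit_interval(self):
        with pytest.raises(ValueError):
            conditional_lambda_params(1, 1, 1.5, 1.0, 0.001, 0.001)

    @pytest.mark.parametrize("mu,c", [(0.3, 1.0), (0.9, 0.4), (0.0, 2.0)])
    def test_matches_grid_integration(self, mu, c):
        """Posterior mean shape/rate agrees with direct 1-D quadrature of
        Poisson(x; lam) * Poisson(y; (1-mu) c lam) * Gamma prior for all
        counts up to 20."""
        a0 = b0 = 0.001
        lam = np.linspace(1e-8, 200, 400001)
        for x in range(0, 21, 4):
            for y in range(0, 21, 4):
                if x + y == 0:
                    # prior-dominated posterior with a near-singular density
                    # at 0; a linear grid cannot resolve it
                    continue
                logp = ((x + y + a0 - 1) * np.log(lam)
                        - lam * (1 + c * (1 - mu) + b0))
                logp -= logp.max()
                w = np.exp(logp)
                oracle = np.trapezoid(w * lam, lam) / np.trapezoid(w, lam)
                shape, rate = conditional_lambda_params(x, y, mu, c, a0, b0)
                assert shape / rate == pytest.approx(oracle, rel=1e-3)


class TestSamplePhi:
    def test_flat_likelihood_limit_is_uniform(self, rng):
        """With no HpaII tags and vanishing rate the conditional is flat."""
        draws = sample_phi(0, 1e-9, rng, size=20000)
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_matches_truncated_gamma_cdf_by_quadrature(self, rng):
        y_sum, lam = 5, 10.0
        draws = sample_phi(y_sum, lam, rng, size=100000)
        grid = np.linspace(0, 1, 4097)
        dens = grid ** y_sum * np.exp(-lam * grid)
        cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws), grid) / draws.size
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_mean_matches_untruncated_gamma_when_mass_inside(self, rng):
        # Gamma(51, rate 100) has essentially all mass below 1
        draws = sample_phi(50, 100.0, rng, size=50000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 51 / 100) < 3 * se

    def test_rejects_bad_inputs(self, rng):
        with pytest.raises(ValueError):
            sample_phi(-1, 1.0, rng)
        with pytest.raises(ValueError):
            sample_phi(float("nan"), 1.0, rng)

    def test_draws_strictly_inside_unit_interval(self, rng):
        draws = sample_phi(0, 1e4, rng, size=10000)  # mass piles up near 0
        assert np.all(draws > 0) and np.all(draws < 1)


class TestFitBayesRegion:
    @pytest.mark.parametrize("x, y", [
        ([50, 50], [0, 0]),
        ([100], [50]),
        ([5], [8]),
        ([10, 3, 7], [5, 2, 1]),
        ([20, 0], [3, 2]),
    ])
    def test_poisson_mode_matches_grid_oracle(self, x, y):
        cfg = BayesConfig(mode="poisson", seed=7)
        s = fit_bayes_region(x, y, 1.0, cfg)
        oracle = grid_posterior_mu_mean(x, y)
        assert abs(s.mu_mean - oracle) <= 3 * batch_means_mcse(s)

    def test_fully_methylated_region_posterior_near_one(self):
        s = fit_bayes_region([50, 50], [0, 0], 1.0,
                             BayesConfig(mode="poisson", seed=1))
        assert s.mu_mean > 0.9
        assert 0.0 < s.mu_mean < 1.0 and s.mu_variance > 0

    def test_posterior_mean_strictly_inside_even_at_truncation_cases(self):
        """Unlike TPE, the posterior never sits exactly on 0 or 1."""
        for x, y in ([[5], [8]], [[10], [0]]):
            s = fit_bayes_region(x, y, 1.0, BayesConfig(seed=3))
            assert 0.0 < s.mu_mean < 1.0
            assert np.all(s.mu_samples > 0) and np.all(s.mu_samples < 1)

    def test_bias_correction_direction(self):
        lo = fit_bayes_region([10], [10], 1.0, BayesConfig(mode="poisson", seed=5))
        hi = fit_bayes_region([10], [10], 2.0, BayesConfig(mode="poisson", seed=5))
        assert hi.mu_mean > lo.mu_mean

    def test_fixed_seed_bit_identical(self):
        a = fit_bayes_region([10, 4], [3, 1], 1.0, BayesConfig(seed=11))
        b = fit_bayes_region([10, 4], [3, 1], 1.0, BayesConfig(seed=11))
        assert a.mu_mean == b.mu_mean and a.mu_variance == b.mu_variance
        assert np.array_equal(a.mu_samples, b.mu_samples)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_bayes_region([0, 0], [0, 0])

    def test_parameter_count_by_mode(self):
        pois = fit_bayes_region([10, 5], [1, 1], 1.0,
                                BayesConfig(mode="poisson", seed=2))
        nb = fit_bayes_region([10, 5], [1, 1], 1.0,
                              BayesConfig(mode="negbin", seed=2))
        assert pois.n_params == 2 + 1      # K lambdas + mu
        assert nb.n_params == 3 * 2 + 1    # (lambda, r, p) per site + mu

    def test_negbin_with_large_fixed_r_reproduces_poisson(self):
        """Pinning every over-dispersion parameter at a large value collapses
        the negative-binomial hierarchy onto the Poisson one.

        At fixed large r the uniform prior on p induces an (almost) flat
        prior on the implied depth lambda = r p / (1 - p), so the reference
        is the Poisson-mode posterior under a flat Gamma(1, ~0) depth prior,
        computed by quadrature.  r cannot be pushed arbitrarily high in this
        check: the (lambda, p) pair then becomes near-deterministically
        coupled and the Gibbs chain mixes at rate ~ (x+y)/r, so a large-but-
        mixable r with chains long enough for a batch-means error estimate
        is used.
        """
        x, y = [12, 8], [4, 6]
        nb = fit_bayes_region(x, y, 1.0,
                              BayesConfig(mode="negbin", fix_r=200.0, seed=9,
                                          burn_in=1000, n_samples=3000))
        oracle = grid_posterior_mu_mean(x, y, a0=1.0, b0=1e-6)
        assert abs(nb.mu_mean - oracle) <= 3 * batch_means_mcse(nb, batch=250)

    def test_parameter_recovery_improves_with_depth(self):
        """Mean absolute error shrinks monotonically over depths 30/100/300
        and is below 0.03 at depth 300."""
        from methylquant.simulate import simulate_methylseq
        errors = {}
        for depth in (30, 100, 300):
            ds = simulate_methylseq(n_regions=60, n_libraries=2, depth=depth,
                                    seed=depth)
            ests, _ = mq.fit_bayes_regions(ds.regions,
                                           config=BayesConfig(seed=depth + 1))
            err = [abs(e.mu - ds.truth[(e.region_id, e.library_id)])
                   for e in ests]
            errors[depth] = np.mean(err)
        assert errors[30] > errors[100] > errors[300]
        assert errors[300] < 0.03


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        chain = rng.normal(size=1000)
        assert gelman_rubin([chain, chain]) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_chains_blow_up(self, rng):
        a = rng.normal(0, 1, 500)
        assert gelman_rubin([a, a + 100]) > 10

    def test_matches_textbook_formula(self, rng):
        chains = rng.normal(size=(4, 200))
        m, n = chains.shape
        means = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean()
        B = n / (m - 1) * ((means - means.mean()) ** 2).sum()
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-10)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))
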