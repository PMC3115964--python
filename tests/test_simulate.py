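"""Synthetic-data generators: distributions, determinism, design contracts."""

import numpy as np
import pytest
from scipy import stats

import methylquant as mq
from methylquant.simulate import (MuDistribution, calibrate_copula_rho,
                                  sample_region_sizes, simulate_correlated_sites,
                                  simulate_discordant, simulate_methylseq,
                                  simulate_replicates, simulate_rrbs)


def region_counts(ds, lib="lib1"):
    x = np.concatenate([r.mspi_counts() for r in ds.regions])
    y = np.concatenate([r.hpaii_counts(lib) for r in ds.regions])
    return x, y


class TestRegionSizes:
    def test_empirical_size_distribution(self, rng):
        ks = sample_region_sizes(100000, rng)
        assert np.mean(ks == 2) == pytest.approx(0.77, abs=0.005)
        assert np.mean(ks <= 5) == pytest.approx(0.95, abs=0.005)
        assert ks.min() >= 2 and ks.max() <= 10

    def test_single_draw(self, rng):
        assert sample_region_sizes(1, rng)[0] >= 2


class TestSimulateMethylseq:
    def test_poisson_marginals_at_fixed_mu(self):
        """Mean HpaII count tracks the thinned rate (1 - mu) * depth."""
        for mu, expected in ((0.0, 50.0), (0.5, 25.0)):
            ds = simulate_methylseq(n_regions=2000, n_libraries=1, depth=50.0,
                                    mu_dist=MuDistribution("fixed", value=mu),
                                    seed=3)
            _, y = region_counts(ds)
            se = y.std(ddof=1) / np.sqrt(y.size)
            assert abs(y.mean() - expected) < 3 * se

    def test_full_methylation_silences_hpaii(self):
        ds = simulate_methylseq(n_regions=500, n_libraries=2, depth=50.0,
                                mu_dist=MuDistribution("fixed", value=1.0),
                                seed=4)
        for lib in ("lib1", "lib2"):
            assert all(c == 0 for r in ds.regions for c in r.hpaii_counts(lib))

    def test_mspi_counts_are_poisson(self):
        """Chi-square goodness of fit of the MspI counts to Poisson(depth)."""
        ds = simulate_methylseq(n_regions=4000, n_libraries=1, depth=8.0, seed=5)
        x, _ = region_counts(ds)
        kmax = int(x.max())
        observed = np.bincount(x, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), 8.0) * x.size
        expected[-1] += (1 - stats.poisson.cdf(kmax, 8.0)) * x.size
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001

    def test_deterministic_and_regenerable_from_params(self):
        a = simulate_methylseq(n_regions=20, seed=9)
        b = simulate_methylseq(n_regions=20, seed=9)
        assert a.truth == b.truth
        assert all(ra.mspi_counts() == rb.mspi_counts()
                   for ra, rb in zip(a.regions, b.regions))
        assert a.params["seed"] == 9 and a.params["depth"] == 50.0

    def test_truth_covers_every_pair_in_unit_interval(self):
        ds = simulate_methylseq(n_regions=30, n_libraries=3, seed=2)
        assert len(ds.truth) == 30 * 3
        assert all(0.0 <= v <= 1.0 for v in ds.truth.values())

    def test_thinned_variant_bounded_by_mspi(self):
        ds = simulate_methylseq(n_regions=300, n_libraries=1, depth=20.0,
                                seed=8, thinned=True)
        x, y = region_counts(ds)
        assert np.all(y <= x)


class TestSimulateDiscordant:
    def test_sigma_zero_reduces_to_basic_design(self):
        ss = np.random.SeedSequence(77)
        [disc] = simulate_discordant(50.0, 0.0, n_datasets=1, n_regions=25,
                                     seed=77)
        basic = simulate_methylseq(n_regions=25, depth=50.0,
                                   seed=np.random.SeedSequence(77).spawn(1)[0])
        assert disc.truth == basic.truth
        assert all(ra.mspi_counts() == rb.mspi_counts()
                   and ra.hpaii_counts("lib3") == rb.hpaii_counts("lib3")
                   for ra, rb in zip(disc.regions, basic.regions))

    def test_lognormal_depth_spread(self):
        """At sigma = 1 the dispersion of HpaII counts far exceeds Poisson;
        the median count stays near the MspI depth (log-normal median)."""
        [ds] = simulate_discordant(300.0, 1.0, n_datasets=1, n_regions=2000,
                                   n_libraries=1, seed=6)
        _, y = region_counts(ds)
        mu_vals = ds.truth_vector()
        site_mu = np.repeat(mu_vals, [r.K for r in ds.regions])
        unmeth = site_mu < 0.02
        logs = np.log(y[unmeth & (y > 0)].astype(float))
        assert np.var(logs) > 0.5  # Poisson(300) alone would give ~1/300
        assert np.median(y[unmeth]) == pytest.approx(300, rel=0.25)


class TestCorrelatedSites:
    def test_comonotone_at_rho_one(self):
        ds = simulate_correlated_sites(1.0, 30.0, n_sites=200, seed=5)
        for r in ds.regions:
            m1 = ds.site_truth[(r.region_id, r.sites[0].site_id)]
            m2 = ds.site_truth[(r.region_id, r.sites[1].site_id)]
            assert m1 == m2

    def test_copula_hits_target_pearson(self):
        ds = simulate_correlated_sites(0.92, 30.0, n_sites=20000, seed=6)
        pairs = np.array([[ds.site_truth[(r.region_id, s.site_id)]
                           for s in r.sites] for r in ds.regions])
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert r == pytest.approx(0.92, abs=0.01)

    def test_copula_preserves_marginals(self, rng):
        dist = MuDistribution(alpha=0.4, beta=0.4)
        ds = simulate_correlated_sites(0.95, 30.0, n_sites=20000,
                                       mu_marginal=dist, seed=7)
        m1 = np.array([ds.site_truth[(r.region_id, r.sites[0].site_id)]
                       for r in ds.regions])
        direct = dist.sample(rng, m1.size)
        assert stats.ks_2samp(m1, direct).pvalue > 0.01

    def test_mspi_fixed_at_depth(self):
        ds = simulate_correlated_sites(0.95, 30.0, n_sites=50, seed=1)
        assert all(c == 30 for r in ds.regions for c in r.mspi_counts())

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_correlated_sites(1.2, 30.0, n_sites=10, seed=0)

    def test_calibration_monotone(self):
        dist = MuDistribution(alpha=0.4, beta=0.4)
        lat = [calibrate_copula_rho(r, dist) for r in (0.5, 0.7, 0.9)]
        assert lat[0] < lat[1] < lat[2] < 1.0


class TestReplicates:
    def test_shared_truth_independent_counts(self):
        a, b = simulate_replicates(50.0, n_regions=100, n_libraries=2, seed=3)
        assert a.truth == b.truth
        xa = np.concatenate([r.mspi_counts() for r in a.regions])
        xb = np.concatenate([r.mspi_counts() for r in b.regions])
        assert not np.array_equal(xa, xb)

    def test_estimates_converge_at_extreme_depth(self):
        a, b = simulate_replicates(1e5, n_regions=100, n_libraries=1, seed=4)
        ta = [e.mu for e in mq.estimate_regions(a.regions, "tpe")]
        tb = [e.mu for e in mq.estimate_regions(b.regions, "tpe")]
        assert np.corrcoef(ta, tb)[0, 1] > 0.999


class TestRrbs:
    def test_full_methylation_silences_t_channel(self):
        ds = simulate_rrbs(50.0, n_regions=200,
                           mu_dist=MuDistribution("fixed", value=1.0), seed=2)
        assert all(s.t_count == 0 for sites in ds.rrbs_sites.values()
                   for s in sites)

    def test_half_methylation_balances_channels(self):
        ds = simulate_rrbs(50.0, n_regions=5000,
                           mu_dist=MuDistribution("fixed", value=0.5), seed=3)
        c = np.array([s.c_count for ss in ds.rrbs_sites.values() for s in ss])
        t = np.array([s.t_count for ss in ds.rrbs_sites.values() for s in ss])
        frac = c.sum() / (c.sum() + t.sum())
        assert frac == pytest.approx(0.5, abs=0.005)
        # total coverage superposes to Poisson(depth) regardless of mu
        assert (c + t).mean() == pytest.approx(50.0, rel=0.01)


def test_mu_distribution_validation():
    with pytest.raises(ValueError):
        MuDistribution(kind="nope")
    with pytest.raises(ValueError):
        MuDistribution(alpha=-1)
    with pytest.raises(ValueError):
        MuDistribution(kind="fixed", value=1.5)
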