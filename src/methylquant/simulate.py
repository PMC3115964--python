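"""Synthetic Methyl-Seq and RRBS data generators with known truth.

Every generator emits a :class:`SimulatedDataset` pairing tag-count tables
with the true methylation level of each (region, library) and the full
parameterization needed to regenerate it bit-exactly.

The default study conditions mirror the simulation designs the estimators
are benchmarked under: 6 tissue libraries x 155 regions (930 methylation
levels), constant design depth per cleavage site, region sizes drawn from
the empirical distribution of the Methyl-Seq genome (77% of regions have
two sites, 95% have at most five), and a bimodal Beta(0.4, 0.4) methylation
density standing in for the empirical microarray beta-value density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .datamodel import Region, SiteCounts
from .estimators import RrbsSiteCounts

__all__ = [
    "MuDistribution",
    "SimulatedDataset",
    "sample_region_sizes",
    "simulate_methylseq",
    "simulate_discordant",
    "simulate_correlated_sites",
    "simulate_replicates",
    "simulate_rrbs",
    "calibrate_copula_rho",
    "DEFAULT_N_REGIONS",
    "DEFAULT_N_LIBRARIES",
]

DEFAULT_N_REGIONS = 155
DEFAULT_N_LIBRARIES = 6

#: Empirical region-size distribution: P(K=2) = 0.77, P(3<=K<=5) = 0.18
#: split uniformly, P(6<=K<=10) = 0.05 split uniformly.
DEFAULT_SIZE_DIST: dict[int, float] = {
    2: 0.77, 3: 0.06, 4: 0.06, 5: 0.06,
    **{k: 0.01 for k in range(6, 11)},
}


@dataclass(frozen=True)
class MuDistribution:
    """Distribution of true methylation levels.

    ``bimodal_beta`` draws Beta(alpha, beta) with both shape parameters
    below one, concentrating mass near 0 and 1 the way genome-wide
    methylation does; ``fixed`` returns a constant; ``empirical_table``
    resamples a supplied table of levels.
    """

    kind: str = "bimodal_beta"
    alpha: float = 0.4
    beta: float = 0.4
    value: float = 0.5
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bimodal_beta", "fixed", "empirical_table"):
            raise ValueError(f"unknown mu distribution kind {self.kind!r}")
        if self.kind == "bimodal_beta" and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError("bimodal_beta needs alpha, beta > 0")
        if self.kind == "fixed" and not 0.0 <= self.value <= 1.0:
            raise ValueError("fixed value must lie in [0,1]")
        if self.kind == "empirical_table" and not self.values:
            raise ValueError("empirical_table needs a non-empty values table")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.kind == "bimodal_beta":
            return rng.beta(self.alpha, self.beta, size=size)
        if self.kind == "fixed":
            return np.full(size, self.value, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        return vals[rng.integers(0, vals.size, size=size)]

    def ppf(self, q) -> np.ndarray:
        """Quantile function (used by the Gaussian copula)."""
        if self.kind == "bimodal_beta":
            return special.betaincinv(self.alpha, self.beta, q)
        if self.kind == "fixed":
            return np.full_like(np.asarray(q, dtype=float), self.value)
        return np.quantile(np.asarray(self.values, dtype=float), q)

    def to_params(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "bimodal_beta":
            d.update(alpha=self.alpha, beta=self.beta)
        elif self.kind == "fixed":
            d.update(value=self.value)
        else:
            d.update(values=list(self.values))
        return d


@dataclass
class SimulatedDataset:
    """Tag-count tables plus ground truth and generator parameters."""

    regions: list[Region]
    truth: dict[tuple[str, str], float]
    params: dict
    rrbs_sites: dict[str, list[RrbsSiteCounts]] = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return self.regions[0].libraries if self.regions else ["lib1"]

    def truth_vector(self, library_ids: Sequence[str] | None = None,
                     region_ids: Sequence[str] | None = None) -> np.ndarray:
        """Truth values in region-major, library-minor order."""
        rids = region_ids or [r.region_id for r in self.regions]
        libs = library_ids or self.libraries
        return np.array([self.truth[(rid, lib)] for rid in rids for lib in libs])


def _as_seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


def sample_region_sizes(n_regions: int, rng: np.random.Generator,
                        size_dist: dict[int, float] | None = None) -> np.ndarray:
    """Draw per-region site counts K from the empirical size distribution."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    dist = size_dist or DEFAULT_SIZE_DIST
    ks = np.array(sorted(dist))
    probs = np.array([dist[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(ks, size=n_regions, p=probs)


def _build_regions(K: np.ndarray, x: np.ndarray, y: np.ndarray,
                   libs: list[str]) -> list[Region]:
    """Assemble Region objects from per-site count arrays.

    ``x``: (total_sites,) MspI counts; ``y``: (total_sites, n_libraries)
    HpaII counts.  Simulated counts are collapsed values, stored on the
    forward strand with zero reverse tags.
    """
    regions = []
    offsets = np.concatenate([[0], np.cumsum(K)])
    for r_idx in range(len(K)):
        sites = []
        for s_idx in range(int(K[r_idx])):
            i = offsets[r_idx] + s_idx
            sites.append(SiteCounts(
                site_id=f"site_{i + 1}", chrom="chrS",
                pos=int(1000 * (r_idx + 1) + 50 * s_idx),
                mspi_fwd=int(x[i]), mspi_rev=0,
                hpaii_fwd={lib: int(y[i, j]) for j, lib in enumerate(libs)},
                hpaii_rev={lib: 0 for lib in libs},
            ))
        regions.append(Region(f"region_{r_idx + 1}", sites))
    return regions


def _simulate_core(n_regions: int, n_libraries: int, depth: float,
                   mu_dist: MuDistribution, bias: np.ndarray,
                   seedseq: np.random.SeedSequence, *,
                   sigma: float = 0.0, thinned: bool = False,
                   mu: np.ndarray | None = None,
                   K: np.ndarray | None = None,
                   size_dist: dict[int, float] | None = None,
                   ) -> tuple[list[Region], np.ndarray, np.ndarray]:
    """Shared generative engine.

    Separate RNG streams for (truth, depth discordance, counts) so that the
    sigma = 0 discordant design reduces bit-exactly to the basic design and
    technical replicates can redraw counts under frozen truth.
    """
    ss_truth, ss_depth, ss_counts = seedseq.spawn(3)
    rng_truth = np.random.default_rng(ss_truth)
    if K is None:
        K = sample_region_sizes(n_regions, rng_truth, size_dist)
    if mu is None:
        mu = mu_dist.sample(rng_truth, (n_regions, n_libraries))
    total = int(K.sum())
    site_region = np.repeat(np.arange(n_regions), K)

    # per-(region, library) HpaII depth; log-normal around the MspI depth
    if sigma > 0:
        rng_depth = np.random.default_rng(ss_depth)
        log_d = rng_depth.normal(np.log(depth), sigma, size=(n_regions, n_libraries))
        hpaii_depth = np.exp(log_d)
    else:
        hpaii_depth = np.full((n_regions, n_libraries), float(depth))

    rng = np.random.default_rng(ss_counts)
    x = rng.poisson(depth, size=total)
    rate = bias[None, :] * (1.0 - mu) * hpaii_depth  # (n_regions, n_libraries)
    if thinned:
        keep = bias[None, :] * (1.0 - mu)
        if np.any(keep > 1):
            raise ValueError("thinned sampling needs c * (1 - mu) <= 1")
        y = rng.binomial(x[:, None], keep[site_region])
    else:
        y = rng.poisson(rate[site_region])
    libs = [f"lib{j + 1}" for j in range(n_libraries)]
    return _build_regions(K, x, y, libs), mu, K


def simulate_methylseq(n_regions: int = DEFAULT_N_REGIONS,
                       n_libraries: int = DEFAULT_N_LIBRARIES,
                       depth: float = 50.0,
                       mu_dist: MuDistribution | None = None,
                       bias: Sequence[float] | None = None,
                       seed=0, *, thinned: bool = False,
                       size_dist: dict[int, float] | None = None
                       ) -> SimulatedDataset:
    """Simulate a Methyl-Seq experiment at constant design depth.

    Per site, the MspI count is Poisson(depth); per library j, the HpaII
    count is Poisson(c_j * (1 - mu) * depth) with mu drawn once per
    (region, library).  ``thinned=True`` instead draws the HpaII count by
    binomial thinning of the realized MspI count — identical marginals
    under the model, useful for thinning-property checks.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu_dist = mu_dist or MuDistribution()
    c = np.ones(n_libraries) if bias is None else np.asarray(bias, dtype=float)
    if c.shape != (n_libraries,) or np.any(c <= 0):
        raise ValueError("bias must give one positive ratio per library")
    regions, mu, K = _simulate_core(n_regions, n_libraries, depth, mu_dist,
                                    c, _as_seedseq(seed), thinned=thinned,
                                    size_dist=size_dist)
    truth = {(r.region_id, lib): float(mu[i, j])
             for i, r in enumerate(regions)
             for j, lib in enumerate(r.libraries)}
    params = {"design": "methylseq", "n_regions": n_regions,
              "n_libraries": n_libraries, "depth": depth,
              "mu_dist": mu_dist.to_params(), "bias": c.tolist(),
              "thinned": thinned, "seed": _seed_repr(seed)}
    return SimulatedDataset(regions=regions, truth=truth, params=params)


def simulate_discordant(depth_mspi: float, sigma: float,
                        n_datasets: int = 100,
                        n_regions: int = DEFAULT_N_REGIONS,
                        n_libraries: int = DEFAULT_N_LIBRARIES,
                        mu_dist: MuDistribution | None = None,
                        seed=0) -> list[SimulatedDataset]:
    """Simulate depth discordance between the MspI and HpaII libraries.

    The HpaII depth of each (region, library) is log-normal around the
    MspI depth: log(depth_HpaII) ~ Normal(log depth_MspI, sigma^2), so the
    median HpaII depth equals the MspI depth at every sigma and sigma = 0
    reduces exactly to :func:`simulate_methylseq`.  Estimators are run
    assuming no discordance, probing their robustness.
    """
    if depth_mspi <= 0 or sigma < 0:
        raise ValueError("depth_mspi must be > 0 and sigma >= 0")
    mu_dist = mu_dist or MuDistribution()
    c = np.ones(n_libraries)
    out = []
    for i, ss in enumerate(_as_seedseq(seed).spawn(n_datasets)):
        regions, mu, K = _simulate_core(n_regions, n_libraries, depth_mspi,
                                        mu_dist, c, ss, sigma=sigma)
        truth = {(r.region_id, lib): float(mu[ri, j])
                 for ri, r in enumerate(regions)
                 for j, lib in enumerate(r.libraries)}
        params = {"design": "discordance", "dataset_index": i,
                  "depth_mspi": depth_mspi, "sigma": sigma,
                  "n_regions": n_regions, "n_libraries": n_libraries,
                  "mu_dist": mu_dist.to_params(), "seed": _seed_repr(seed)}
        out.append(SimulatedDataset(regions=regions, truth=truth, params=params))
    return out


def calibrate_copula_rho(rho: float, mu_dist: MuDistribution,
                         n_quad: int = 48) -> float:
    """Latent Gaussian correlation giving Pearson correlation ``rho``.

    For a Gaussian copula with identical marginals F, the Pearson
    correlation of (F^-1(Phi(z1)), F^-1(Phi(z2))) is a monotone function
    of the latent correlation; it is computed by Gauss-Hermite quadrature
    and inverted with a root bracket.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0,1], got {rho}")
    if rho == 1.0:
        return 1.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w = weights / weights.sum()
    q = stats.norm.cdf(nodes)
    m = mu_dist.ppf(np.clip(q, 1e-12, 1 - 1e-12))
    mean = float(w @ m)
    var = float(w @ (m - mean) ** 2)
    if var == 0:
        raise ValueError("degenerate marginal distribution")

    z1 = nodes[:, None]
    wv = nodes[None, :]

    def pearson(rho_z: float) -> float:
        z2 = rho_z * z1 + np.sqrt(1.0 - rho_z ** 2) * wv
        m2 = mu_dist.ppf(np.clip(stats.norm.cdf(z2), 1e-12, 1 - 1e-12))
        e12 = float(w @ (m[:, None] * m2) @ w)
        return (e12 - mean ** 2) / var

    if rho == 0.0:
        return 0.0
    return float(optimize.brentq(lambda rz: pearson(rz) - rho,
                                 0.0, 1.0 - 1e-10, xtol=1e-8))


def simulate_correlated_sites(rho: float, depth: float, n_sites: int = 2000,
                              mu_marginal: MuDistribution | None = None,
                              seed=0) -> SimulatedDataset:
    """Simulate two-site regions with correlated methylation levels.

    (mu1, mu2) come from a Gaussian copula calibrated so their Pearson
    correlation is ``rho``, with identical marginals; MspI counts are
    fixed at the design depth (x_i = round(depth)) and HpaII counts are
    Poisson((1 - mu_i) * depth).  Used to compare site-level with
    region-level estimation.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu_marginal = mu_marginal or MuDistribution()
    n_pairs = n_sites // 2
    if n_pairs < 1:
        raise ValueError("need at least two sites")
    ss_truth, _, ss_counts = _as_seedseq(seed).spawn(3)
    rng_truth = np.random.default_rng(ss_truth)
    rho_z = calibrate_copula_rho(rho, mu_marginal)
    z1 = rng_truth.standard_normal(n_pairs)
    if rho_z >= 1.0:
        z2 = z1
    else:
        z2 = rho_z * z1 + np.sqrt(1.0 - rho_z ** 2) * rng_truth.standard_normal(n_pairs)
    q = np.clip(stats.norm.cdf(np.stack([z1, z2], axis=1)), 1e-12, 1 - 1e-12)
    mu = mu_marginal.ppf(q)  # (n_pairs, 2)

    rng = np.random.default_rng(ss_counts)
    x = np.full(2 * n_pairs, int(round(depth)))
    y = rng.poisson((1.0 - mu.reshape(-1)) * depth)[:, None]
    K = np.full(n_pairs, 2)
    regions = _build_regions(K, x, y, ["lib1"])
    # the two sites of a pair have individual truths; the region truth is
    # their common marginal draw only when rho = 1, so store site truths too
    truth = {(r.region_id, "lib1"): float(mu[i].mean())
             for i, r in enumerate(regions)}
    params = {"design": "correlated", "rho": rho, "rho_latent": rho_z,
              "depth": depth, "n_sites": 2 * n_pairs,
              "mu_dist": mu_marginal.to_params(), "seed": _seed_repr(seed)}
    ds = SimulatedDataset(regions=regions, truth=truth, params=params)
    ds.site_truth = {  # type: ignore[attr-defined]
        (r.region_id, s.site_id): float(mu[i, k])
        for i, r in enumerate(regions) for k, s in enumerate(r.sites)}
    return ds


def simulate_replicates(depth: float, n_regions: int = DEFAULT_N_REGIONS,
                        n_libraries: int = DEFAULT_N_LIBRARIES,
                        mu_dist: MuDistribution | None = None,
                        seed=0) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two technical replicates: one truth table, independent counts."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu_dist = mu_dist or MuDistribution()
    c = np.ones(n_libraries)
    ss_truth, ss_a, ss_b = _as_seedseq(seed).spawn(3)
    rng_truth = np.random.default_rng(ss_truth)
    K = sample_region_sizes(n_regions, rng_truth)
    mu = mu_dist.sample(rng_truth, (n_regions, n_libraries))
    out = []
    for rep, ss in (("A", ss_a), ("B", ss_b)):
        regions, _, _ = _simulate_core(n_regions, n_libraries, depth, mu_dist,
                                       c, ss, mu=mu, K=K)
        truth = {(r.region_id, lib): float(mu[ri, j])
                 for ri, r in enumerate(regions)
                 for j, lib in enumerate(r.libraries)}
        params = {"design": "replicates", "replicate": rep, "depth": depth,
                  "n_regions": n_regions, "n_libraries": n_libraries,
                  "mu_dist": mu_dist.to_params(), "seed": _seed_repr(seed)}
        out.append(SimulatedDataset(regions=regions, truth=truth, params=params))
    return out[0], out[1]


def simulate_rrbs(depth: float, n_regions: int = DEFAULT_N_REGIONS,
                  mu_dist: MuDistribution | None = None, seed=0
                  ) -> SimulatedDataset:
    """Simulate RRBS bisulfite counts: C ~ Poisson(mu * depth) and
    T ~ Poisson((1 - mu) * depth) independently per site."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu_dist = mu_dist or MuDistribution()
    ss_truth, _, ss_counts = _as_seedseq(seed).spawn(3)
    rng_truth = np.random.default_rng(ss_truth)
    K = sample_region_sizes(n_regions, rng_truth)
    mu = mu_dist.sample(rng_truth, n_regions)
    site_region = np.repeat(np.arange(n_regions), K)
    rng = np.random.default_rng(ss_counts)
    c_counts = rng.poisson(mu[site_region] * depth)
    t_counts = rng.poisson((1.0 - mu[site_region]) * depth)

    rrbs_sites: dict[str, list[RrbsSiteCounts]] = {}
    offsets = np.concatenate([[0], np.cumsum(K)])
    truth = {}
    for r_idx in range(n_regions):
        rid = f"region_{r_idx + 1}"
        sl = slice(offsets[r_idx], offsets[r_idx + 1])
        rrbs_sites[rid] = [RrbsSiteCounts(f"site_{i + 1}", int(c_counts[i]),
                                          int(t_counts[i]))
                           for i in range(sl.start, sl.stop)]
        truth[(rid, "lib1")] = float(mu[r_idx])
    params = {"design": "rrbs", "depth": depth, "n_regions": n_regions,
              "mu_dist": mu_dist.to_params(), "seed": _seed_repr(seed)}
    return SimulatedDataset(regions=[], truth=truth, params=params,
                            rrbs_sites=rrbs_sites)


def _seed_repr(seed):
    if isinstance(seed, np.random.SeedSequence):
        return {"entropy": seed.entropy, "spawn_key": list(seed.spawn_key)}
    return seed
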