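"""Bayesian hierarchical Gamma-Poisson model of region methylation.

The generative model for a region of K cleavage sites with methylation
level mu, observed in one HpaII library with depth-bias ratio c:

    x_i | lambda_i        ~ Poisson(lambda_i)                 (MspI tags)
    y_i | lambda_i, mu    ~ Poisson(c * (1 - mu) * lambda_i)  (HpaII tags)

HpaII tags arise by Poisson thinning: each fragment survives the
methylation-sensitive digestion independently with probability (1 - mu),
so the HpaII count is Poisson with the thinned rate.  The per-site depth
lambda_i is given a prior in one of two modes:

* ``poisson`` mode — lambda_i ~ Gamma(0.001, 0.001), a vague conjugate
  prior; the counts are marginally (nearly) Poisson.
* ``negbin`` mode (default) — lambda_i ~ Gamma(shape r_i, scale
  p_i / (1 - p_i)), so x_i is marginally negative-binomial NB(r_i, p_i)
  with over-dispersion parameter r_i; as r_i -> infinity the model
  collapses to the Poisson case.

Priors: mu ~ Uniform(0,1), p_i ~ Uniform(0,1), r_i ~ Gamma(0.01, 0.01).

Inference is a native Gibbs-within-Metropolis sampler.  lambda_i and
phi = 1 - mu have exact conjugate full conditionals (Gamma, and Gamma
truncated to (0,1) respectively); r_i and p_i are updated by adaptive
random-walk Metropolis on log r_i and logit p_i.  Multiple chains start
from deterministically staggered initial values; the potential scale
reduction factor (R-hat) on mu is reported, not enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

from .datamodel import Region, DepthBias, MethylEstimate

__all__ = [
    "BayesConfig",
    "PosteriorSummary",
    "conditional_lambda_params",
    "sample_phi",
    "fit_bayes_region",
    "fit_bayes_regions",
    "gelman_rubin",
]

_PHI_EPS = 1e-12


@dataclass(frozen=True)
class BayesConfig:
    """Sampler configuration.

    Defaults follow the standard protocol: three chains, 500 burn-in
    iterations, 500 retained iterations per chain.  ``fix_r`` pins every
    over-dispersion parameter at a constant (useful for checking the
    Poisson limit at very large r); ``None`` samples them.
    """

    mode: str = "negbin"
    n_chains: int = 3
    burn_in: int = 500
    n_samples: int = 500
    seed: int = 0
    lambda_prior_shape: float = 0.001
    lambda_prior_rate: float = 0.001
    r_prior_shape: float = 0.01
    r_prior_rate: float = 0.01
    rhat_threshold: float = 1.1
    fix_r: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("poisson", "negbin"):
            raise ValueError(f"mode must be 'poisson' or 'negbin', got {self.mode!r}")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.burn_in < 1 or self.n_samples < 1:
            raise ValueError("burn_in and n_samples must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior summary of one region-library fit."""

    mu_mean: float
    mu_variance: float
    mu_samples: np.ndarray  # pooled post-burn-in draws, all chains
    lambda_means: np.ndarray  # posterior mean depth per site
    rhat: float
    n_params: int
    converged: bool

    def to_estimate(self, region_id: str = "", library_id: str = "") -> MethylEstimate:
        return MethylEstimate(region_id=region_id, library_id=library_id,
                              mu=self.mu_mean, variance=self.mu_variance,
                              method="bayes")


def conditional_lambda_params(x_i: float, y_i: float, mu: float, c: float,
                              prior_shape: float, prior_rate: float
                              ) -> tuple[float, float]:
    """Gamma full-conditional parameters for one site's depth lambda_i.

    Conjugacy of the Gamma prior with the two Poisson likelihood terms
    gives shape = x_i + y_i + prior_shape and rate = 1 + c*(1-mu) +
    prior_rate.  In negbin mode the prior parameters are the Gamma implied
    by (r_i, p_i): shape r_i, rate (1-p_i)/p_i.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must lie in [0,1], got {mu}")
    if c <= 0 or prior_shape <= 0 or prior_rate <= 0:
        raise ValueError("c and prior parameters must be positive")
    return (x_i + y_i + prior_shape, 1.0 + c * (1.0 - mu) + prior_rate)


def sample_phi(y_sum, lambda_eff_sum, rng: np.random.Generator, size=None):
    """Draw phi = 1 - mu from its truncated-Gamma full conditional.

    Under the Uniform(0,1) prior on mu, the full conditional of phi is
    Gamma(y_sum + 1, rate = lambda_eff_sum) truncated to (0,1), where
    lambda_eff_sum = c * sum(lambda_i).  Sampling is by inverse CDF using
    the regularized incomplete gamma function; draws are clipped a hair
    inside (0,1) so mu never touches the endpoints.

    Accepts scalars or broadcasting arrays; ``size`` requests that many
    draws for scalar parameters.
    """
    y_sum = np.asarray(y_sum, dtype=float)
    lam = np.asarray(lambda_eff_sum, dtype=float)
    if not (np.all(np.isfinite(y_sum)) and np.all(np.isfinite(lam))):
        raise ValueError("sample_phi needs finite inputs")
    if np.any(y_sum < 0) or np.any(lam <= 0):
        raise ValueError("y_sum must be >= 0 and lambda_eff_sum > 0")
    a = y_sum + 1.0
    mass_below_1 = special.gammainc(a, lam)  # P(Gamma(a, rate=lam) < 1)
    shape = np.broadcast_shapes(a.shape, lam.shape) if size is None else size
    u = rng.random(shape if shape != () else None)
    phi = special.gammaincinv(a, u * mass_below_1) / lam
    phi = np.clip(phi, _PHI_EPS, 1.0 - _PHI_EPS)
    return float(phi) if phi.ndim == 0 else phi


def _log_gamma_pdf(lam, shape, rate):
    return shape * np.log(rate) - special.gammaln(shape) \
        + (shape - 1.0) * np.log(lam) - rate * lam


def _run_batch(x: np.ndarray, y: np.ndarray, c: np.ndarray,
               config: BayesConfig, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Run the sampler on B same-size regions at once.

    x, y: (B, K) counts; c: (B,) depth-bias ratios.  Returns
    (mu_draws of shape (n_chains, n_samples, B), lambda_means (B, K)).
    Regions are conditionally independent given their own parameters, so
    batching changes nothing in the model, only the stream of random draws.
    """
    B, K = x.shape
    C = config.n_chains
    negbin = config.mode == "negbin"
    cb = c[None, :, None]  # broadcast to (C, B, K)

    # deterministically staggered starting points per chain
    mu = np.tile(((np.arange(C) + 1.0) / (C + 1.0))[:, None], (1, B))
    lam = np.tile(np.maximum(x, 1.0)[None, :, :], (C, 1, 1))
    if negbin:
        r0 = 10.0 if config.fix_r is None else config.fix_r
        r = np.full((C, B, K), r0)
        # start p where the implied Gamma mean r*p/(1-p) equals the lambda
        # start max(x, 1); at r = 10 and x = 10 this is the familiar 0.5
        m0 = np.maximum(x, 1.0)[None, :, :]
        p = np.broadcast_to(m0 / (m0 + r0), (C, B, K)).copy()
        log_r, logit_p = np.log(r), special.logit(p)
        step_r, step_p = 0.5, 0.5  # adaptive RW scales (burn-in only)
    ar, br = config.r_prior_shape, config.r_prior_rate

    n_iter = config.burn_in + config.n_samples
    mu_draws = np.empty((C, config.n_samples, B))
    lam_accum = np.zeros((B, K))
    xy = (x + y)[None, :, :]

    for it in range(n_iter):
        # lambda_i | rest ~ Gamma(x+y+prior_shape, 1 + c(1-mu) + prior_rate)
        if negbin:
            pr_shape, pr_rate = r, (1.0 - p) / p
        else:
            pr_shape = config.lambda_prior_shape
            pr_rate = config.lambda_prior_rate
        rate = 1.0 + cb * (1.0 - mu)[:, :, None] + pr_rate
        lam = rng.gamma(xy + pr_shape, size=(C, B, K)) / rate
        np.clip(lam, 1e-300, None, out=lam)

        # phi = 1 - mu | rest ~ truncated Gamma
        phi = sample_phi(y.sum(axis=1)[None, :], c[None, :] * lam.sum(axis=2), rng)
        mu = 1.0 - phi

        if negbin and config.fix_r is None:
            # Metropolis on log r_i: target Gamma(lam; r, (1-p)/p) * prior(r),
            # plus the log-scale Jacobian
            prop = log_r + step_r * rng.standard_normal(log_r.shape)
            r_new = np.exp(prop)
            beta = (1.0 - p) / p
            delta = (_log_gamma_pdf(lam, r_new, beta)
                     - _log_gamma_pdf(lam, r, beta)
                     + (ar - 1.0) * (prop - log_r) - br * (r_new - r)
                     + (prop - log_r))
            accept = np.log(rng.random(delta.shape)) < delta
            log_r = np.where(accept, prop, log_r)
            r = np.exp(log_r)
            if it < config.burn_in:
                step_r *= math.exp(0.05 * (accept.mean() - 0.44))
        if negbin:
            # Metropolis on logit p_i under the Uniform(0,1) prior
            prop = logit_p + step_p * rng.standard_normal(logit_p.shape)
            p_new = special.expit(prop)
            delta = (_log_gamma_pdf(lam, r, (1.0 - p_new) / p_new)
                     - _log_gamma_pdf(lam, r, (1.0 - p) / p)
                     + np.log(p_new * (1.0 - p_new)) - np.log(p * (1.0 - p)))
            accept = np.log(rng.random(delta.shape)) < delta
            logit_p = np.where(accept, prop, logit_p)
            p = special.expit(logit_p)
            if it < config.burn_in:
                step_p *= math.exp(0.05 * (accept.mean() - 0.44))

        if it >= config.burn_in:
            mu_draws[:, it - config.burn_in, :] = mu
            lam_accum += lam.mean(axis=0)

    return mu_draws, lam_accum / config.n_samples


def _summarize(mu_draws_b: np.ndarray, lambda_means_b: np.ndarray,
               K: int, config: BayesConfig) -> PosteriorSummary:
    pooled = mu_draws_b.reshape(-1)
    rhat = gelman_rubin(mu_draws_b)
    n_params = 3 * K + 1 if config.mode == "negbin" else K + 1
    return PosteriorSummary(
        mu_mean=float(pooled.mean()),
        mu_variance=float(pooled.var(ddof=1)),
        mu_samples=pooled.copy(),
        lambda_means=lambda_means_b.copy(),
        rhat=rhat,
        n_params=n_params,
        converged=bool(rhat <= config.rhat_threshold),
    )


def fit_bayes_region(x: Sequence[int], y: Sequence[int], c: float = 1.0,
                     config: BayesConfig | None = None) -> PosteriorSummary:
    """Fit the hierarchical model to one region in one HpaII library.

    ``x`` are the K collapsed MspI counts, ``y`` the K collapsed HpaII
    counts, ``c`` the library's depth-bias ratio.  Site-level fitting is
    the K = 1 case.  Fixed config seed gives bit-identical output.
    """
    config = config or BayesConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D counts")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not c > 0:
        raise ValueError(f"depth-bias ratio must be positive, got {c}")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("all-zero MspI and HpaII counts carry no information")
    rng = np.random.default_rng(config.seed)
    mu_draws, lam_means = _run_batch(x[None, :], y[None, :],
                                     np.array([c]), config, rng)
    return _summarize(mu_draws[:, :, 0], lam_means[0], x.size, config)


def fit_bayes_regions(regions: Sequence[Region],
                      bias: dict[str, DepthBias] | None = None,
                      config: BayesConfig | None = None
                      ) -> tuple[list[MethylEstimate], list[PosteriorSummary]]:
    """Fit every (region, library) pair, batching same-size regions.

    Regions are independent given their own parameters, so all pairs with
    the same number of sites K share one vectorized sampler run; this is
    purely a speed device.  Returns estimates and full posterior summaries
    in the same (region-major, library-minor) order.
    """
    config = config or BayesConfig()
    tasks = []  # (region_id, library_id, x, y, c)
    for region in regions:
        x = region.mspi_counts()
        for lib in region.libraries:
            c = bias[lib].c if bias and lib in bias else 1.0
            tasks.append((region.region_id, lib, x, region.hpaii_counts(lib), c))

    by_k: dict[int, list[int]] = {}
    for idx, t in enumerate(tasks):
        by_k.setdefault(len(t[2]), []).append(idx)

    summaries: list[PosteriorSummary | None] = [None] * len(tasks)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(by_k))
    for (K, idxs), ss in zip(sorted(by_k.items()), children):
        x = np.array([tasks[i][2] for i in idxs], dtype=float)
        y = np.array([tasks[i][3] for i in idxs], dtype=float)
        c = np.array([tasks[i][4] for i in idxs], dtype=float)
        mu_draws, lam_means = _run_batch(x, y, c, config,
                                         np.random.default_rng(ss))
        for b, i in enumerate(idxs):
            summaries[i] = _summarize(mu_draws[:, :, b], lam_means[b], K, config)

    estimates = [s.to_estimate(region_id=t[0], library_id=t[1])
                 for t, s in zip(tasks, summaries)]
    return estimates, summaries  # type: ignore[return-value]


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (R-hat) across parallel chains.

    ``chains`` is an (m, n) array of m >= 2 chains with n draws each.
    Computed as sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance; identical chains give a
    value just below 1.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    m, n = arr.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    within = arr.var(axis=1, ddof=1).mean()
    between = n * arr.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))
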