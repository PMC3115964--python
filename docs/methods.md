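# Methods

## The quantification problem

Methyl-Seq interrogates DNA methylation at 5′-CCGG-3′ sites by digesting the
same sample with two restriction enzymes: MspI cuts every CCGG, while HpaII
cuts only unmethylated CCGG. After size selection and sequencing, each
cleavage site *i* carries an MspI tag count *x<sub>i</sub>* (a depth control)
and, per tissue library *j*, an HpaII tag count *y<sub>ij</sub>* (an
unmethylation signal). Because samples are heterogeneous cell mixtures, the
methylation level μ of a region is a continuous fraction in [0, 1], not a
binary state. Neighbouring sites (most digested fragments are 35–75 bp) are
grouped into regions assumed to share one μ; regions are small — in the
reference genome-wide tag data 77% contain exactly two sites and 95% at most
five, which is why the estimators must work at very small K.

RRBS measures the same quantity by bisulfite conversion: at a covered
cytosine, *x* reads retain C (methylated) and *y* reads convert to T, giving
the direct proportion estimate *x*/(*x*+*y*), pooled over a region as
Σ*x<sub>i</sub>* / Σ(*x<sub>i</sub>*+*y<sub>i</sub>*).

## Estimators

**Binary call.** The original Methyl-Seq analysis calls a region
unmethylated when its mean collapsed HpaII tag count exceeds 1, using MspI
tags only to define assayable sites (≥ 4 MspI reads on either strand). Both
strands of a site witness the same digestion event but may be unevenly
sequenced, so each site's count is collapsed to the larger of the forward
and reverse tag counts — for MspI once, and per library for HpaII.

**Truncated Proportional Estimate (TPE).** Model the counts as
*x<sub>i</sub>* ~ Poisson(λ<sub>i</sub>) and, by Poisson thinning with
survival probability (1−μ), *y<sub>i</sub>* ~ Poisson((1−μ)λ<sub>i</sub>).
The maximum-likelihood estimate — identical under the Poisson and the
negative-binomial count assumption — is

    μ̂ = max(0, 1 − Σy_i / Σx_i),

truncated at 0 because sampling noise can push the HpaII total above the
MspI total. TPE is simple and assumption-light, but it is biased toward 0 at
low methylation, piles exact point masses at 0 and 1, and carries no usable
variance: with K mostly 2, the observed-information approximation is not
trustworthy.

**Bayesian hierarchical model.** The generative hierarchy is

    x_i | λ_i      ~ Poisson(λ_i)
    y_i | λ_i, μ   ~ Poisson(c (1−μ) λ_i)
    λ_i            ~ Gamma(r_i, scale p_i/(1−p_i))   (negbin mode)
                   ~ Gamma(0.001, 0.001)             (poisson mode)
    μ, p_i         ~ Uniform(0, 1),   r_i ~ Gamma(0.01, 0.01)

In negbin mode the marginal count is negative-binomial NB(r<sub>i</sub>,
p<sub>i</sub>); r<sub>i</sub> is the over-dispersion parameter and the model
collapses to the Poisson case as r<sub>i</sub> → ∞. The NB(r, p) ↔
Gamma(shape r, scale p/(1−p)) convention used throughout means large p
implies deep coverage. Priors are deliberately vague and all exposed in
`BayesConfig`. The posterior mean of μ is the estimate and the posterior
variance accompanies it — the practical motivation for the extra machinery,
since downstream association analyses need site- and region-specific
uncertainty under heterogeneous coverage.

### Sampler

A native Gibbs-within-Metropolis scheme (no external MCMC engine):

* λ<sub>i</sub> | rest ~ Gamma(x<sub>i</sub>+y<sub>i</sub>+shape₀,
  1 + c(1−μ) + rate₀) — exact conjugate update, with (shape₀, rate₀) the
  fixed prior in poisson mode or (r<sub>i</sub>, (1−p<sub>i</sub>)/p<sub>i</sub>)
  in negbin mode.
* φ = 1−μ | rest ~ Gamma(Σy<sub>i</sub>+1, c·Σλ<sub>i</sub>) truncated to
  (0, 1), drawn by inverse CDF via the regularized incomplete gamma
  function; draws are clipped 1e−12 inside the interval, so the posterior
  mean is strictly inside (0, 1) — the Bayesian estimator never reproduces
  TPE's point masses at the boundaries.
* r<sub>i</sub>, p<sub>i</sub> (negbin): random-walk Metropolis on log r and
  logit p, with scalar step sizes adapted toward 44% acceptance during
  burn-in only (so the post-burn-in kernel is fixed and draws are a valid
  Markov chain).

Defaults: 3 chains, 500 burn-in + 500 retained iterations per chain, negbin
mode. Chains start from deterministically staggered values — chain k at
μ = k/(n_chains+1), λ<sub>i</sub> = max(x<sub>i</sub>, 1), r<sub>i</sub> = 10
and p<sub>i</sub> = max(x<sub>i</sub>,1)/(max(x<sub>i</sub>,1)+r<sub>i</sub>),
so the implied prior mean of λ<sub>i</sub> matches its start — which keeps
runs bit-reproducible under a fixed seed. Convergence is summarized by the
potential scale reduction factor (R-hat) on μ and reported, not enforced;
regions are flagged, never dropped. With 3K+1 parameters (K+1 in poisson
mode) and K mostly 2, mixing is fast.

`fit_bayes_regions` batches all (region, library) fits with equal K into one
vectorized sampler run. Regions are conditionally independent given their
own parameters, so batching changes only the pairing of random draws with
regions, not the model; each batch spawns its own child seed, and results
remain bit-reproducible for a fixed seed and region set.

### Sequencing-depth bias

HpaII libraries are typically sequenced shallower than the MspI reference
(≈3M vs ≈10M tags in the reference data set). Per-region bias is
unobservable, so the genome-wide ratio of CGG-aligned tag totals defines a
per-library constant c = (HpaII total)/(MspI total); the HpaII rate becomes
c(1−μ)λ<sub>i</sub> and the adjusted TPE is max(0, 1 − (Σy/Σx)/c). The
orientation matters: c < 1 (shallow HpaII) must *raise* μ̂, and the opposite
convention silently inverts the correction — hence c is data the caller
supplies (`compute_depth_bias`, bias TSV), not hidden policy. Because the
HpaII genome-wide total itself reflects methylation, the adjustment is
approximate by construction.

## Synthetic data

The generators emulate the benchmark designs end to end; they are the
package's test bed, not a fixture store.

* **Truth.** μ per (region, library) from a bimodal Beta(0.4, 0.4) by
  default. The reference analyses drew μ from the empirical density of
  Infinium microarray beta values, which is not published as a table; a
  symmetric sub-uniform Beta concentrating mass near 0 and 1 is the standard
  stand-in for genome-wide methylation and is stated explicitly in every
  run's parameters. Quantities that depend on the exact μ density (overall
  correlation levels, the Bayes−TPE gap) shift with this choice; qualitative
  contrasts (orderings, variance asymmetry) do not.
* **Region sizes.** K categorical with P(K=2)=0.77, P(K∈{3,4,5})=0.18 split
  evenly, P(K∈{6..10})=0.05 split evenly — matching the published 77%/95%
  quantiles of the genome-wide region-size distribution.
* **Counts.** x<sub>i</sub> ~ Poisson(λ₀) at constant design depth λ₀
  (default 50; sweeps use 30–350 as stated per experiment), y<sub>ij</sub> ~
  Poisson(c<sub>j</sub>(1−μ)λ₀) drawn marginally — equivalent in law to
  binomial thinning of the realized x<sub>i</sub>, which is available behind
  `thinned=True` for thinning-property tests.
* **Depth discordance.** log(depth_HpaII) ~ Normal(log λ₀, σ²) drawn
  independently per (region, library) — each HpaII library is a separate
  sequencing run, so regional depth fluctuations are not shared across
  libraries. σ = 0 reduces bit-exactly to the basic design (the depth
  stream is seeded separately from the count stream).
* **Correlated neighbours.** Pairs (μ₁, μ₂) from a Gaussian copula with
  identical Beta marginals; the latent correlation is calibrated to the
  requested Pearson correlation by Gauss–Hermite quadrature plus root
  bracketing (deterministic, no simulation in the calibration). ρ = 1 is
  the comonotone limit μ₁ = μ₂. MspI counts are held fixed at the design
  depth in this design, isolating the site-vs-region comparison.
* **Replicates.** Two datasets share one truth table; counts are redrawn
  independently. Consistency is the Pearson correlation of paired
  estimates.
* **RRBS.** C ~ Poisson(μλ₀) and T ~ Poisson((1−μ)λ₀) independently per
  site, so total coverage is Poisson(λ₀) regardless of μ.

Every generator consumes a `numpy` `SeedSequence` discipline: one master
seed, separate spawned streams per stage, bit-identical regeneration from
the recorded parameters. What the generators do **not** model: fragment-size
selection bias, GC-driven depth variation, inter-site autocorrelation within
the basic designs, paired-end fragment structure, and bisulfite conversion
failure — so passing benchmarks demonstrate estimator behaviour under the
stated count model, not robustness to every artifact of real libraries.

## Evaluation

* Pearson/Spearman correlation against truth (or microarray beta values),
  pooled across libraries by default, per-library on request.
* Two estimators scored against the same reference are compared with the
  Williams/Steiger t-test for dependent correlations sharing one variable
  (df = n−3); the implied 3×3 correlation matrix must be positive definite.
  A resampling oracle in the test suite guards the choice of variant.
* ROC/AUC against beta values dichotomized at 0.6, computed as the
  Mann–Whitney statistic with tied pairs counting ½. Orientation is an
  explicit flag because raw HpaII counts predict *un*methylation while μ̂
  predicts methylation; an implicit sign would silently report 1−AUC.
* Infinium renormalization: beta = b/(a+b) after subtracting the
  negative-control median from each channel and flooring at zero; when both
  channels floor, the value is missing (NaN), not an error.

## Numerical choices and edge cases

* TPE with Σx = 0 raises (no MspI signal — the caller decides imputation);
  sites with zero collapsed MspI count inside an assayable region are
  retained with x<sub>i</sub> = 0 and handled by every estimator.
* All-zero x *and* y raises in the Bayesian fit (no information).
* Truncated-Gamma draws: inverse CDF on u·F(1) with F the regularized
  incomplete gamma; numerically stable down to Σy = 0 with tiny rates
  (flat-likelihood limit → uniform draws).
* λ draws are floored at 1e−300 to avoid log(0) in the Metropolis targets.
* R-hat uses the classic formula sqrt(((n−1)/n·W + B/n)/W); identical
  chains give √((n−1)/n) ≈ 1 − 1/(2n).
* Binary call at mean count exactly 1 is methylated (the rule is a strict
  inequality).

## Benchmark scales

The shipped experiment drivers default to the full study conditions
(155 regions × 6 libraries; 10 datasets per discordance level at MspI depth
30; 2000 sites per correlation level; depth sweep over 40/80/150/300;
2000 sites per fixed-μ variance profile). The vectorized sampler fits all
930 region-library pairs of a depth-50 dataset in a few seconds, so the
complete benchmark suite runs on a laptop; `ExperimentConfig.scale`
multiplies region and dataset counts for quicker exploratory runs.

## Known limitations

* The depth-bias constant conflates methylation with depth; an iterative
  re-adjustment after quantification is a known improvement left out by
  design.
* μ is constant within a region by assumption; real methylation can
  fluctuate between neighbouring sites, and no autocorrelation prior is
  fitted.
* The Poisson-limit check of negbin mode runs at a large-but-finite fixed r
  (r = 200): at much larger r the (λ<sub>i</sub>, p<sub>i</sub>) pair is
  near-deterministically coupled and any finite Gibbs chain mixes at rate
  ~ (x+y)/r.
* Real-data comparisons (published AUCs and correlations against Infinium
  arrays) require the external tag-count and array downloads; the readers
  accept those formats but no such data ships here.
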