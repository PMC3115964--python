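# methylquant

Statistical quantification of DNA methylation levels from next-generation
sequencing tag counts: **Methyl-Seq** (paired MspI/HpaII restriction
digestion libraries) and **RRBS** (bisulfite C/T read counts).

## The problem

Methyl-Seq digests the same DNA sample with MspI (cuts every 5′-CCGG-3′
site) and HpaII (cuts only *unmethylated* CCGG). After size selection and
sequencing, each cleavage site *i* carries an MspI tag count
*x<sub>i</sub>* — a methylation-insensitive depth control — and, per tissue
library, an HpaII tag count *y<sub>i</sub>* that shrinks as methylation
rises. Because samples are heterogeneous cell mixtures, the estimand is a
continuous methylation fraction μ ∈ [0, 1] per region (a cluster of
neighbouring sites sharing one level, usually only K = 2 of them), not a
binary state — and shotgun sampling noise at typical depths makes naive
counting unreliable.

`methylquant` implements three estimators behind one data model:

* **binary** — the original region call: unmethylated iff the mean
  collapsed HpaII count exceeds 1;
* **tpe** — the Truncated Proportional Estimate, the maximum-likelihood
  estimate under a Poisson-thinning count model
  (*y<sub>i</sub>* ~ Poisson((1−μ)λ<sub>i</sub>)):

      μ̂ = max(0, 1 − (Σyᵢ / Σxᵢ) / c),

  where c is an optional per-library HpaII/MspI sequencing-depth ratio;
* **bayes** — a hierarchical Gamma-Poisson model (x<sub>i</sub> | λ<sub>i</sub>
  ~ Poisson(λ<sub>i</sub>), y<sub>i</sub> | λ<sub>i</sub>, μ ~
  Poisson(c(1−μ)λ<sub>i</sub>), λ<sub>i</sub> ~ Gamma, making the counts
  marginally negative-binomial with over-dispersion r<sub>i</sub>), fitted
  by a native Gibbs-within-Metropolis sampler; returns the posterior mean
  *and* variance of μ, and never produces TPE's point masses at 0 and 1.

For RRBS the estimator is the pooled proportion Σx<sub>i</sub>/Σ(x<sub>i</sub>+y<sub>i</sub>)
of C over total reads. The package also ships the full benchmarking
machinery: synthetic-data generators with known truth (constant-depth
designs, depth sweeps, log-normal depth discordance, correlated
neighbouring sites, technical replicates, RRBS), and evaluation statistics
(correlations, a dependent-correlation t-test, Mann-Whitney ROC/AUC against
dichotomized microarray beta values, replicate consistency, Infinium beta
renormalization). See `docs/methods.md` for the model details and design
choices.

## Worked example

```sh
python examples/02_depth50_benchmark.py
```

simulates 6 tissue libraries × 155 regions at sequencing depth 50 per
cleavage site (930 true methylation levels drawn from a bimodal Beta), runs
TPE and the Bayesian model on every region-library pair, and prints:

```
n = 930 region-library methylation levels at depth 50
Pearson r with truth:  TPE = 0.9804   Bayes = 0.9815
TPE estimates exactly 0 or 1: 18.6%   Bayes: 0.0%
dependent-correlation test of the gap: t = 2.46, p = 0.014
```

Read: at depth 50 both estimators track truth tightly; the Bayesian
posterior means correlate slightly but significantly better (the gap is
tested with the Williams/Steiger t-test for two correlations sharing the
truth vector), and nearly a fifth of TPE's estimates sit exactly on the
boundary values 0 or 1 — the truncation artifact the Bayesian model is
designed to remove. The other examples cover single-region estimation with
depth-bias correction (`01`), robustness to MspI/HpaII depth discordance
(`03`), and the variance asymmetry of Methyl-Seq versus the symmetry of
RRBS (`04`).

A thin CLI wraps the same library:

```sh
methylquant simulate --design basic --seed 7 --out sim/
methylquant estimate --method bayes --counts sim/counts.tsv --out est.tsv
methylquant evaluate --estimates est.tsv --truth sim/truth.tsv --out eval.json
methylquant experiment --design discordance --scale 0.1 --out run/
```

Input tag-count tables are TSV with columns
`chrom pos region_id site_id mspi_fwd mspi_rev` plus
`hpaii_<lib>_fwd`/`hpaii_<lib>_rev` per library (1-based positions); sites
with fewer than 4 MspI reads on both strands are dropped as unassayable.

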