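"""Accuracy benchmark on a simulated Methyl-Seq experiment at depth 50.

Simulates 6 tissue libraries x 155 regions (930 true methylation levels,
bimodal Beta truth, empirical region sizes), estimates every level with TPE
and the Bayesian model, and compares both against the known truth.
"""

import numpy as np

from methylquant import (BayesConfig, dependent_corr_test, estimate_regions,
                         fit_bayes_regions, simulate_methylseq)

ds = simulate_methylseq(depth=50.0, seed=7)

tpe_est = estimate_regions(ds.regions, method="tpe")
bayes_est, _ = fit_bayes_regions(ds.regions, config=BayesConfig(seed=8))

truth = np.array([ds.truth[(e.region_id, e.library_id)] for e in tpe_est])
tpe_mu = np.array([e.mu for e in tpe_est])
bayes_mu = np.array([e.mu for e in bayes_est])

r_tpe = np.corrcoef(tpe_mu, truth)[0, 1]
r_bayes = np.corrcoef(bayes_mu, truth)[0, 1]
r12 = np.corrcoef(tpe_mu, bayes_mu)[0, 1]
t, p = dependent_corr_test(r_bayes, r_tpe, r12, truth.size)

print(f"n = {truth.size} region-library methylation levels at depth 50")
print(f"Pearson r with truth:  TPE = {r_tpe:.4f}   Bayes = {r_bayes:.4f}")
print(f"TPE estimates exactly 0 or 1: {np.mean((tpe_mu == 0) | (tpe_mu == 1)):.1%}"
      f"   Bayes: {np.mean((bayes_mu == 0) | (bayes_mu == 1)):.1%}")
print(f"dependent-correlation test of the gap: t = {t:.2f}, p = {p:.2g}")
print("Both estimators track truth tightly; the Bayesian gap is small but",
      "systematic, and it avoids TPE's point masses at the boundaries.")
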