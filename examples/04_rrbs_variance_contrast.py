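"""Variance asymmetry of Methyl-Seq versus the symmetry of RRBS.

At fixed depth, the spread of the Methyl-Seq TPE is much larger at low
methylation than at high methylation (the MspI count is a noisy denominator
whose fluctuations matter most when the HpaII signal is large), while the
RRBS proportion x/(x+y) treats the C and T channels symmetrically.
"""

import numpy as np

from methylquant import (MuDistribution, estimate_regions, rrbs_estimate,
                         simulate_methylseq, simulate_rrbs)

print(f"{'true mu':>8} {'SD of TPE (Methyl-Seq)':>24} {'SD of RRBS':>12}")
for mu in (0.1, 0.9):
    fixed = MuDistribution("fixed", value=mu)
    ms = simulate_methylseq(n_regions=2000, n_libraries=1, depth=50.0,
                            mu_dist=fixed, seed=int(10 * mu))
    tpe_sd = np.std([e.mu for e in estimate_regions(ms.regions, "tpe")], ddof=1)
    rb = simulate_rrbs(50.0, n_regions=2000, mu_dist=fixed, seed=int(10 * mu))
    rrbs_sd = np.std([rrbs_estimate(s).mu for s in rb.rrbs_sites.values()],
                     ddof=1)
    print(f"{mu:>8.1f} {tpe_sd:>24.4f} {rrbs_sd:>12.4f}")

print("\nTPE's spread inflates several-fold at mu = 0.1 versus mu = 0.9;",
      "the RRBS proportion's spread is essentially the same at both ends.")
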