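"""Simulate an HTS-Kin pool experiment and recover relative rate constants.

Builds a realistic specificity landscape over all 4096 leader hexamers,
depletes the pool by internal competition to 5/15/30% conversion, sequences
each timepoint to 5 million reads, and re-estimates every variant's relative
k_cat/K_m from the counts.
"""

import numpy as np
from scipy import stats

from htskin import krel, simulate

truth = simulate.assign_true_krel(model=simulate.realistic_landscape(), seed=11)
table = simulate.simulate_pool_counts(truth, seed=11)
rates = krel.krel_from_counts(table)

rho = stats.spearmanr(rates.k_rel.to_numpy(), truth.true_krel).statistic
ok = rates.data["flag"] == "ok"
k_ok = rates.k_rel[ok]

print(f"variants measured: {ok.sum()} of {len(rates.data)} "
      f"({(~ok).sum()} censored: too slow to deplete detectably)")
print(f"rank correlation with assigned truth: {rho:.3f}")
print(f"k_rel span (fastest/slowest measured): {k_ok.max() / k_ok.min():.0f}-fold")
print(f"reference leader AAAAAG k_rel: {rates.k_rel['AAAAAG']:.3f} (calibrated)")

top = krel.top_fraction(rates, q=0.01)
print(f"fastest 1% ({len(top)} variants), first five: {top[:5]}")
# The span shows how strongly the six leader positions tune cleavage; the
# rank correlation is the fidelity of the sequencing-based rate recovery.
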