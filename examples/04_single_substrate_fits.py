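"""Fit single-substrate assays: turnover kinetics, binding, and dissociation.

Generates noiseless curves at the measured parameters of the optimal (AU)
and slowest (GG) N(-2)N(-1) leader constructs, refits them, and tabulates
fold changes; then resolves a dissociation time course into fast (ES) and
slow (ES*) phases.
"""

import numpy as np

from htskin import kinfit, simulate

NM = 1e-9
S_GRID = np.geomspace(10 * NM, 1000 * NM, 10)  # 10 nM - 1 uM substrate

fits = {}
for name, (kcat, ratio) in {"AU": (0.12, 7e6), "GG": (0.07, 0.5e6),
                            "AU_D3": (0.261, 26e6)}.items():
    data = simulate.simulate_initial_rates(kcat, kcat / ratio, 1 * NM, S_GRID)
    fits[name] = kinfit.fit_mm(data, E0=1 * NM)
    f = fits[name]
    print(f"{name:6s} kcat = {f.kcat:.3f} s^-1   "
          f"kcat/Km = {f.kcat_over_Km / 1e6:.1f} x 10^6 M^-1 s^-1")

folds = kinfit.fold_changes(fits).set_index(["numerator", "denominator",
                                             "parameter"])
print(f"\nAU / GG specificity ratio: "
      f"{folds.loc[('AU', 'GG', 'kcat_over_Km'), 'fold']:.0f}-fold "
      "(cost of two RCCA pairs at the cleavage site)")
print(f"AU_D3 / AU: {folds.loc[('AU_D3', 'AU', 'kcat_over_Km'), 'fold']:.1f}-fold "
      "(gain from deleting the 3' RCCA tail)")

for name, kd_nm in {"AU": 35.0, "GG": 63.0}.items():
    data = simulate.simulate_binding(kd_nm * NM, 0.9,
                                     np.geomspace(2.5 * NM, 200 * NM, 8))
    fit = kinfit.fit_binding(data)
    print(f"{name} binding: Kd = {fit.Kd / NM:.0f} nM (Bmax {fit.Bmax:.2f})")

t = np.linspace(0, 600, 25)
diss = simulate.simulate_dissociation(frac_fast=0.5, k_fast=0.05, k_slow=1e-5,
                                      t_grid=t, noise_sd=0.005, seed=1)
fit = kinfit.fit_dissociation(diss)
print(f"\nGG-like dissociation: {fit.n_phases} phases; "
      f"ES (fast) = {fit.es_fraction:.2f}, ES* (stable) = {fit.es_star_fraction:.2f}")
# Binding differs only ~2-fold while kcat/Km differs 14-fold: the RCCA-paired
# leader binds, but half of it stalls in the uncommitted ES state.
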