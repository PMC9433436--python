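# htskin

Sequence specificity and kinetics of RNase P precursor-tRNA processing, from
high-throughput sequencing kinetics (HTS-Kin).

Bacterial RNase P removes the 5′ leader from every precursor tRNA (ptRNA) in
the cell, and the six leader nucleotides N(−6)…N(−1) adjacent to the cleavage
site tune its specificity constant k<sub>cat</sub>/K<sub>m</sub> over roughly
two orders of magnitude. HTS-Kin measures all 4096 leader hexamer variants at
once: a randomized substrate pool reacts under internal competition, the
residual (unreacted) pool is sequenced at several fractions of reaction, and
each variant's relative rate constant follows from its log-depletion. This
package is for enzymologists and sequence-analysis folk who want that whole
analysis — and the downstream specificity modelling — as tested, importable
Python.

## What it computes

**Relative rate constants (internal competition).** With read proportions
p<sub>i</sub>(0) at the start and p<sub>i</sub>(f) when a fraction f of total
substrate has reacted, the fraction of variant *i* remaining is
F<sub>i</sub> = (1 − f) · p<sub>i</sub>(f)/p<sub>i</sub>(0), and

&nbsp;&nbsp;&nbsp;&nbsp;k<sub>rel,i</sub> = ln F<sub>i</sub> / ln F<sub>ref</sub>

calibrated so the genomically encoded reference leader (AAAAAG) reads exactly 1.
Estimates from multiple timepoints and replicates are combined by
inverse-variance weighting on the log scale (see `docs/methods.md` for the
pool-anchored normalization that keeps the reference's counting noise out of
every denominator).

**Specificity model (PWM + pairwise interactions).** ln k<sub>rel</sub> is
regressed on per-position base indicators with sum-to-zero identifiability
constraints, plus pairwise interaction indicators selected by iterative
rounds of regression with a |T| > 3.5 admission threshold:

&nbsp;&nbsp;&nbsp;&nbsp;ln k<sub>rel</sub> ~ Σ<sub>i</sub> (a<sub>i</sub>A<sub>i</sub> + c<sub>i</sub>C<sub>i</sub> + g<sub>i</sub>G<sub>i</sub> + u<sub>i</sub>U<sub>i</sub>) + Σ<sub>n</sub> α<sub>n</sub>I<sub>n</sub>

**Pairing anti-determinants.** A dynamic program scores the maximum number of
Watson–Crick + G·U wobble pairs an antiparallel duplex can form between a
leader window and the 3′ RCCA tail (bulges allowed, no register assumed);
leaders reaching two pairs extend the acceptor stem and inhibit the
ES → ES\* conformational step.

**Single-substrate kinetics.** Weighted Michaelis–Menten fits
(v = k<sub>cat</sub>[E]₀[S]/(K<sub>m</sub>+[S])), equilibrium binding
isotherms (y = B<sub>max</sub>[E]/(K<sub>d</sub>+[E])), two-phase
dissociation fits resolving ES (fast) from ES\* (slow), and construct
fold-change tables with propagated errors.

A first-class simulator (`htskin.simulate`) generates pool-depletion read
counts and assay curves with known ground truth, which is how every estimator
here is validated.

## Worked example

```bash
python examples/04_single_substrate_fits.py
```

```
AU     kcat = 0.120 s^-1   kcat/Km = 7.0 x 10^6 M^-1 s^-1
GG     kcat = 0.070 s^-1   kcat/Km = 0.5 x 10^6 M^-1 s^-1
AU_D3  kcat = 0.261 s^-1   kcat/Km = 26.0 x 10^6 M^-1 s^-1

AU / GG specificity ratio: 14-fold (cost of two RCCA pairs at the cleavage site)
AU_D3 / AU: 3.7-fold (gain from deleting the 3' RCCA tail)
AU binding: Kd = 35 nM (Bmax 0.90)
GG binding: Kd = 63 nM (Bmax 0.90)

GG-like dissociation: 2 phases; ES (fast) = 0.50, ES* (stable) = 0.50
```

The AU construct (optimal A(−2)U(−1) leader) and the GG construct (slowest
dinucleotide, two base pairs with the RCCA tail) differ 14-fold in
k<sub>cat</sub>/K<sub>m</sub> but only ~2-fold in K<sub>d</sub>; the
dissociation fit shows why — half of the bound GG substrate sits in the
loosely bound ES state rather than the committed ES\* complex.

The other examples walk the pool pipeline end to end:

```bash
python examples/01_pool_kinetics_recovery.py   # simulate, sequence, recover k_rel
python examples/02_specificity_model.py        # PWM + interaction selection
python examples/03_pairing_antideterminants.py # duplex scoring and leader census
```

A thin CLI wraps the same calls for shell pipelines (`htskin simulate-pool`,
`count`, `krel`, `fit-specificity`, `pairing`, `fit-kinetics`, `report`).

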