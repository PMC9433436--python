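# Methods

## Internal competition kinetics

When many substrates compete for the same limiting enzyme at sub-saturating
concentrations, each variant's unreacted amount decays as
F_i(c) = exp(−k_i c), where k_i is the variant's k_cat/K_m relative to a
common scale and c is a shared exposure integral (the time integral of free
enzyme concentration). The total fraction reacted f satisfies
Σ w_i F_i = 1 − f for initial pool weights w_i. Ratios of log-depletions are
therefore exactly ratios of specificity constants, independent of c — this is
the identity the whole pool analysis rests on, and the simulator realizes it
literally: `solve_exposure` root-finds c for a requested f (bisection-safe
Brent on [0, 50/min k_i], tolerance 1e−10) and `sample_reads` draws
multinomial reads with probabilities ∝ w_i F_i.

### The estimator and its normalizer

From counts, F_i = (1 − f) p_i(f)/p_i(0) with a 0.5 pseudocount per cell
(Anscombe-style; configurable). The textbook single-timepoint estimator
k_rel,i = ln F_i / ln F_ref is exact on noise-free data, but its denominator
is a single variant's log-depletion estimated from ~1/4096 of the reads. At
the earliest sampled timepoint (f = 0.05) the reference's depletion signal
(~1%) is smaller than its counting noise (~4% at 5×10⁶ reads/sample), so the
reference-anchored form is numerically unstable exactly where the experiment
starts. Each timepoint is instead normalized by the read-weighted pool
log-depletion

    s_t = − Σ_i p_i(0) ln F_i,t ,

which equals c_t · (Σ p_i(0) k_i): proportional to the exposure with a
proportionality constant that is fixed within a replicate (the start-weighted
pool mean rate). Per-timepoint estimates ln(−ln F_i / s_t) are combined
across timepoints and replicates by inverse-variance weighting (variances
from binomial counting error, 1/count at both samples, delta method through
the double log), and the combined table is rescaled once so the reference
leader reads exactly 1. On noise-free data this reproduces
ln F_i / ln F_ref identically (a unit test verifies the algebra, including
the pool-sum ratio form of the published estimator); on sampled data it keeps
the reference's noise out of every denominator and contributes it only once,
as a common calibration term included in the reported standard errors.

### Censoring

A variant whose proportion apparently *rises* between samples (F_i ≥ 1 after
pseudocounts) carries no rate information at that timepoint; its F is capped
at 1 − 1/(2·reads) and the observation is excluded from the weighted mean.
Only when every observation of a variant is censored is the variant flagged
`censored_low` — its reported k_rel then rests on the censoring bound. Flagged
variants are retained in all tables, and the specificity fit excludes them
with an explicit count. At the default depth this affects a handful of the
very slowest variants; the largest recovery errors concentrate in the slow
tail generally, because slow variants barely change their read counts over
the sampled conversion window.

## Specificity model

ln k_rel is fit by least squares to per-position base indicators plus
pairwise interaction indicators. The four indicators at a position sum to
one, so per-position coefficients are identified by a sum-to-zero constraint
(each coefficient is log-enrichment relative to the position average); a
reference-base ("baseline") constraint is also available and yields identical
predictions. The design is reduced to 18 free main-effect columns through a
block contrast matrix, fit with statsmodels OLS/WLS, and expanded back with
its covariance, so every reported coefficient carries a T-value. Weighted
fitting by 1/SE² is available but off by default: the reference row has zero
calibration SE by construction, and raw inverse-variance weights would let it
dominate.

Interaction terms come from a 240-candidate universe (15 position pairs × 16
base pairs). Selection is iterative forward selection: each round scores
every remaining candidate by the t-value its coefficient would have in a
joint refit with the current model (computed exactly via
Frisch–Waugh residualization, vectorized over candidates), admits the
strongest candidate if |T| > 3.5, and stops when none clears the bar
(convergence cap 20 rounds). One admission per round matters: scoring
candidates only marginally within a round lets a single real coupling drag
its sibling indicators (same position pair, shared base) over the threshold
on leakage alone, which biases coefficients and can make the true term's
column collinear with the admitted set. Forward selection recovers planted
couplings of |α| ≥ 0.5 at ln-noise σ = 0.1 in every seeded replicate with
mean main-effect error ~0.002, and admits no terms under a main-effects-only
truth at the same noise. An exact fit is handled by flooring the residual
variance at 1e−24 so a perfectly explained candidate gets a huge finite T
rather than 0/0.

Sequence logos are frequency matrices with per-position information content
IC = 2 + Σ p log₂ p bits (uniform background); a minimal matplotlib renderer
draws letter heights, since logo drawing is presentation, not inference.

## Leader / 3′-RCCA pairing

The pairing score is the maximum number of base pairs an antiparallel duplex
can form between a leader window (default the cleavage-proximal
N(−2)N(−1); configurable up to N(−4)) and the tail (default ACCA; use GCCA
for an R = G discriminator), allowing Watson–Crick and G·U wobble pairs and
unpaired bulges on either strand. No structural register is assumed and no
thermodynamics is scored — the biological claim is about pairing *potential*
(two or more pairs extend the acceptor stem and inhibit ES → ES\*), so
cardinality is the right currency. Antiparallel geometry reduces the problem
to a longest-common-subsequence-style dynamic program against the reversed
tail; a brute-force enumeration over all monotone matchings serves as the
oracle in tests (exact agreement over all 256 windows × tail). Traceback ties
resolve toward pairs closest to the cleavage site. Leader strings are 5′→3′
throughout; dinucleotide labels are N(−2)N(−1) (so "GU" means G at −2, U at
−1 — both orderings score ≥ 2 against ACCA, so classification does not hinge
on the convention).

## Single-substrate fits

* Initial rates: linear regression of reacted fraction vs time restricted to
  the ≤ 10% linear regime (≥ 3 qualifying points required), times [S]₀.
* Michaelis–Menten: nonlinear least squares of v = kcat·E₀·S/(Km+S), weights
  1/SD² from replicate standard deviations with the SD floored at its 10th
  percentile (a zero-SD point must not carry infinite weight), unweighted
  when replicates are absent. kcat/Km and its SE come from the full parameter
  covariance. [E] in the binding isotherm is total enzyme — with substrate
  near-trace the hyperbolic form in total enzyme is adequate, and a
  tight-binding quadratic is deliberately not applied by default.
* Dissociation: A_slow·e^(−k_slow t) + A_fast·e^(−k_fast t), selected
  against a single exponential by AICc, with fallback to one phase on
  non-convergence. The fast amplitude is read as the loosely bound encounter
  complex (ES), the slow amplitude as the isomerized committed complex (ES*).
* All fitters nondimensionalize internally (substrate/enzyme scaled by the
  grid maximum, time by the last point) because molar-unit parameters are
  O(1e−8) and defeat trust-region step scaling; covariances are mapped back
  through the exact Jacobian. Initial guesses come from half-saturation
  points with a log-spaced multi-start ladder on non-convergence.
* Fold changes between named constructs propagate SEs as relative errors in
  quadrature.

## The simulator: what it emulates, and what it does not

Defaults are the study conditions: all 4⁶ = 4096 hexamer variants, uniform
initial weights (a log-normal skew option emulates transcription bias),
sampled fractions of reaction 0.05/0.15/0.30 (the ~5–30% conversion window),
two technical replicates, and 5×10⁶ reads per sample — depth is not stated
by the source experiment, so it was chosen once so the median variant gets
>1000 reads and kept fixed. The bundled realistic landscape places
positive determinants at A(−2) and C(−4) with weaker U(−5)/U(−6), penalizes
G at N(−1)…N(−4), and adds interaction penalties (α ≈ −1) for the
RCCA-pairing dinucleotides GU/GG/UG at N(−2)N(−1); coefficients were chosen
once so the k_rel distribution spans roughly 100-fold and the couplings
dominate single-position effects. Assay curves use homoscedastic Gaussian
noise with three replicates.

Not emulated: RT-PCR amplification bias, sequencing substitution errors, PCR
duplicates, gel-purification losses, or leader stem-loop structure beyond
the hexamer. Passing recovery tests therefore demonstrate estimator
correctness under multinomial counting noise, not robustness to those
library-preparation artifacts.

## Problem sizes and reproducibility

The test suite and acceptance analyses run the full 4096-variant pool;
specificity recovery uses 20 seeded replicates at ln-noise σ = 0.1; noisy
kinetic-fit calibration uses 50 seeded replicates at 5% noise. All
randomness flows through numpy Generators seeded explicitly; identical seeds
give bit-identical count tables and fit inputs.

## Known limitations

* Censored-low variants have no finite lower rate bound; their reported
  value is the bound implied by half a read of depletion.
* Combining timepoints assumes the start-weighted pool mean rate is constant
  within a replicate, which holds exactly for the shared-t0 design but would
  be violated if t0 samples differed between timepoints.
* Forward selection inherits the usual caveats of stepwise regression on
  heteroscedastic data: on sampled (rather than idealized) pools it admits
  small-|α| terms beyond the planted couplings, and slow-tail noise
  attenuates the largest penalties.
* The duplex scorer counts pairs; it does not rank two-pair helices by
  stability, and distal leader secondary structure is out of scope.
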