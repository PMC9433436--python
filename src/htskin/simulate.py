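"""Synthetic HTS-Kin data: competitive pool depletion and single-substrate assays.

A randomized substrate pool reacting with limiting enzyme under internal
competition depletes each variant i by first-order kinetics in a shared
exposure integral c (the time integral of free-enzyme concentration scaled by
the reference specificity constant):

    F_i(c) = exp(-k_i * c),     sum_i w_i F_i = 1 - f

where k_i is the variant's relative k_cat/K_m, w_i its initial pool fraction
and f the total fraction of substrate reacted. Sequencing the residual pool
at depth D is a multinomial draw with probabilities proportional to w_i F_i.
The simulator solves for the exposure c that realizes a requested f, making
assigned k_i values an exact ground truth for the downstream estimator.

Single-substrate assays (initial rates, equilibrium binding, dissociation
time courses) are generated from their standard functional forms with
optional homoscedastic Gaussian noise and replicate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import seqio
from .seqio import (
    CONSTRUCT_DOWNSTREAM,
    CONSTRUCT_UPSTREAM,
    LeaderVariant,
    N_VARIANTS,
    all_variants,
    variant_index,
)
from .specificity import SpecificityModel

#: The genomically encoded ptRNA(met) leader used to calibrate k_rel.
REFERENCE_LEADER = "AAAAAG"

#: Default sampled fractions of reaction (the ~5-30% conversion window).
DEFAULT_F_TARGETS = (0.05, 0.15, 0.30)

#: Default sequencing depth per sample (reads); median variant gets >100 reads.
DEFAULT_DEPTH = 5_000_000


def enumerate_pool() -> list[LeaderVariant]:
    """All 4096 leader hexamers N(-6)..N(-1), lexicographic, with pool indices."""
    return [LeaderVariant(sequence=s, index=i) for i, s in enumerate(all_variants())]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated pool experiment."""

    variants: list[str]
    true_krel: np.ndarray
    weights: np.ndarray
    seed: int = 0
    depth: int = DEFAULT_DEPTH
    reference: str = REFERENCE_LEADER

    def __post_init__(self):
        self.true_krel = np.asarray(self.true_krel, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variants) != N_VARIANTS:
            raise ValueError(f"expected {N_VARIANTS} variants")
        if not np.all(np.isfinite(self.true_krel)) or np.any(self.true_krel <= 0):
            raise ValueError("true_krel must be finite and positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("initial weights must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant": self.variants, "true_krel": self.true_krel,
             "weight": self.weights}
        )


@dataclass
class DepletionState:
    """Pool state at one sampled timepoint of the competition reaction."""

    exposure: float
    frac_unreacted: np.ndarray  # per-variant F_i in (0, 1]
    f: float  # total fraction reacted


def uniform_weights() -> np.ndarray:
    return np.full(N_VARIANTS, 1.0 / N_VARIANTS)


def lognormal_weights(sigma: float, seed: int) -> np.ndarray:
    """Log-normally perturbed initial pool weights (transcription bias)."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=N_VARIANTS)
    return w / w.sum()


def assign_true_krel(
    model: SpecificityModel | None = None,
    table: Mapping[str, float] | np.ndarray | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    depth: int = DEFAULT_DEPTH,
) -> SimulationTruth:
    """Build a SimulationTruth from a specificity model or an explicit table.

    Model-driven truth evaluates the model's ln(k_rel) prediction on every
    hexamer and exponentiates; either way the result is rescaled so the
    reference leader AAAAAG has true_krel exactly 1.
    """
    variants = all_variants()
    if model is not None and table is not None:
        raise ValueError("give either a model or a table, not both")
    if model is not None:
        ln_k = model.predict(variants)
        if not np.all(np.isfinite(ln_k)):
            raise ValueError("model produced non-finite predictions")
        krel = np.exp(ln_k)
    elif table is not None:
        if isinstance(table, Mapping):
            krel = np.array([float(table[v]) for v in variants])
        else:
            krel = np.asarray(table, dtype=float)
    else:
        krel = np.ones(N_VARIANTS)
    krel = krel / krel[variant_index(REFERENCE_LEADER)]
    w = uniform_weights() if weights is None else np.asarray(weights, dtype=float)
    return SimulationTruth(variants=variants, true_krel=krel, weights=w,
                           seed=seed, depth=depth)


def realistic_landscape() -> SpecificityModel:
    """A realistic specificity landscape for the randomized leader pool.

    Positive determinants A(-2) and C(-4) with weaker U(-5)/U(-6); G is
    penalized at N(-1)..N(-4); the N(-2)N(-1) dinucleotides GU, GG and UG that
    can pair with the 3' RCCA carry additional interaction penalties. The
    resulting k_rel distribution spans roughly two orders of magnitude.
    """
    from .specificity import InteractionTerm

    model = SpecificityModel()
    raw = {
        -6: {"U": 0.15},
        -5: {"U": 0.20},
        -4: {"C": 0.55, "G": -0.45},
        -3: {"G": -0.30},
        -2: {"A": 0.50, "G": -0.50},
        -1: {"U": 0.35, "G": -0.55},
    }
    for pos, effects in raw.items():
        col = np.array([effects.get(b, 0.0) for b in "ACGU"])
        model.main_effects[pos] = col - col.mean()  # sum-to-zero per position
    model.interactions = [
        InteractionTerm((-2, -1), ("G", "U"), alpha=-1.0),
        InteractionTerm((-2, -1), ("G", "G"), alpha=-1.0),
        InteractionTerm((-2, -1), ("U", "G"), alpha=-0.9),
    ]
    return model


def _total_unreacted(truth: SimulationTruth, c: float) -> float:
    return float(np.dot(truth.weights, np.exp(-truth.true_krel * c)))


def solve_exposure(truth: SimulationTruth, f_target: float,
                   tol: float = 1e-10) -> DepletionState:
    """Root-find the exposure c at which the pool is f_target reacted.

    sum_i w_i exp(-k_i c) is strictly decreasing in c from 1 toward 0, so the
    root is unique; brentq brackets it on [0, 50/min(k_i)].
    """
    if not 0.0 <= f_target < 1.0:
        raise ValueError(f"f_target must be in [0, 1), got {f_target}")
    if f_target == 0.0:
        return DepletionState(exposure=0.0, frac_unreacted=np.ones(N_VARIANTS), f=0.0)
    c_max = 50.0 / float(truth.true_krel.min())
    c = brentq(lambda x: _total_unreacted(truth, x) - (1.0 - f_target),
               0.0, c_max, xtol=tol, rtol=4 * np.finfo(float).eps)
    F = np.exp(-truth.true_krel * c)
    return DepletionState(exposure=float(c), frac_unreacted=F, f=f_target)


def sample_reads(
    state: DepletionState,
    truth: SimulationTruth,
    depth: int | None = None,
    seed: int | None = None,
    expected: bool = False,
) -> np.ndarray:
    """Sequence the residual pool: multinomial counts over variants.

    Probabilities are proportional to w_i * F_i. With `expected=True` the
    exact expected proportions times depth are returned instead of a draw
    (the infinite-depth limit used by oracle tests).
    """
    depth = truth.depth if depth is None else depth
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = truth.weights * state.frac_unreacted
    p = p / p.sum()
    if expected:
        return p * depth
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return rng.multinomial(depth, p)


def simulate_pool_counts(
    truth: SimulationTruth,
    f_targets: Sequence[float] = DEFAULT_F_TARGETS,
    replicates: int = 2,
    depth: int | None = None,
    seed: int | None = None,
    expected: bool = False,
) -> seqio.PoolCountTable:
    """Full pool experiment: an f=0 reference plus each f target, per replicate."""
    depth = truth.depth if depth is None else depth
    seed = truth.seed if seed is None else seed
    rng_seed = np.random.SeedSequence(seed)
    child_seeds = iter(rng_seed.spawn(replicates * (len(f_targets) + 1)))
    cols, meta = {}, []
    for rep in range(1, replicates + 1):
        for f in (0.0, *f_targets):
            state = solve_exposure(truth, f)
            counts = sample_reads(state, truth, depth=depth,
                                  seed=next(child_seeds), expected=expected)
            if expected:
                counts = np.round(counts).astype(np.int64)
            name = f"rep{rep}_f{f:g}"
            cols[name] = counts
            meta.append({"sample": name, "replicate": f"rep{rep}", "f": f})
    counts_df = pd.DataFrame(cols, index=truth.variants)
    return seqio.PoolCountTable(counts=counts_df.astype(np.int64),
                                samples=pd.DataFrame(meta))


def counts_to_reads(counts: np.ndarray, variants: Sequence[str]) -> list[str]:
    """Expand a count column into amplicon-style reads (DNA alphabet)."""
    reads = []
    for v, n in zip(variants, counts):
        read = (CONSTRUCT_UPSTREAM + v + CONSTRUCT_DOWNSTREAM).replace("U", "T")
        reads.extend([read] * int(n))
    return reads


def write_pool_fastq(table: seqio.PoolCountTable, directory: str | Path) -> list[Path]:
    """One FASTQ per sample reproducing the count table under re-extraction."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in table.sample_ids:
        path = directory / f"{sample}.fastq"
        seqio.write_fastq(path, counts_to_reads(table.counts[sample].to_numpy(),
                                                list(table.counts.index)))
        paths.append(path)
    return paths


def write_truth(truth: SimulationTruth, csv_path: str | Path) -> None:
    """Serialize the truth table plus a YAML sidecar of run parameters."""
    csv_path = Path(csv_path)
    truth.to_frame().to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({
        "seed": int(truth.seed), "depth": int(truth.depth),
        "reference": truth.reference, "n_variants": len(truth.variants),
    }))


def _maybe_noise(y: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return y
    return y + rng.normal(0.0, noise_sd, size=y.shape)


def simulate_initial_rates(
    kcat: float,
    Km: float,
    E0: float,
    S_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Michaelis-Menten initial rates v = kcat*E0*S/(Km+S) over a substrate grid.

    Units are caller-consistent (v in concentration/time of E0 and S). Default
    three replicates per concentration.
    """
    if min(kcat, Km, E0) <= 0:
        raise ValueError("kcat, Km and E0 must be positive")
    rng = np.random.default_rng(seed)
    S = np.asarray(S_grid, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        v = kcat * E0 * S / (Km + S)
        rows.append(pd.DataFrame({"x": S, "y": _maybe_noise(v, noise_sd, rng),
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def simulate_binding(
    Kd: float,
    Bmax: float,
    E_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Equilibrium binding isotherm y = Bmax*E/(Kd+E) over an enzyme titration."""
    if min(Kd, Bmax) <= 0:
        raise ValueError("Kd and Bmax must be positive")
    rng = np.random.default_rng(seed)
    E = np.asarray(E_grid, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        y = Bmax * E / (Kd + E)
        rows.append(pd.DataFrame({"x": E, "y": _maybe_noise(y, noise_sd, rng),
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def simulate_dissociation(
    frac_fast: float,
    k_fast: float,
    k_slow: float,
    t_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Two-phase dissociation of prebound complexes, normalized to t = 0.

    bound(t) = (1-frac_fast) exp(-k_slow t) + frac_fast exp(-k_fast t); the
    fast phase reports the loosely bound encounter complex (ES), the slow
    phase the isomerized committed complex (ES*).
    """
    if not 0.0 <= frac_fast <= 1.0:
        raise ValueError("frac_fast must be in [0, 1]")
    if not k_fast > k_slow >= 0.0:
        raise ValueError("need k_fast > k_slow >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        bound = (1 - frac_fast) * np.exp(-k_slow * t) + frac_fast * np.exp(-k_fast * t)
        rows.append(pd.DataFrame({"x": t, "y": _maybe_noise(bound, noise_sd, rng),
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)
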