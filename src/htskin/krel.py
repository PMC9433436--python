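"""Relative rate constants from internal competition kinetics.

When many substrates compete for the same limiting enzyme, each variant's
unreacted fraction falls exponentially in a shared exposure, so the ratio of
log-depletions of two variants equals the ratio of their specificity
constants k_cat/K_m. With read proportions p_i(0) at the start of the
reaction and p_i(f) when a total fraction f of substrate has reacted, the
fraction of variant i remaining is

    F_i = (1 - f) * p_i(f) / p_i(0)

and the relative rate constant, calibrated to a reference leader, is

    k_rel,i = ln F_i / ln F_ref.

Because the reference is a single variant with ~1/4096 of the reads, its own
log-depletion is the noisiest term in that ratio, and at early timepoints its
counting noise can exceed its depletion signal outright. Each timepoint is
therefore normalized by the read-weighted pool log-depletion

    s_t = -sum_i p_i(0) ln F_i,t

which is exactly proportional to the shared kinetic exposure (the
proportionality constant, the pool-average rate under start weights, is the
same at every timepoint of a replicate) and is estimated from the full
sequencing depth. Per-timepoint estimates ln(-ln F_i / s_t) are combined by
inverse-variance weighting and the combined table is calibrated so the
reference leader reads exactly 1 — which reproduces ln F_i / ln F_ref
identically on noise-free data while keeping the reference's noise out of
every per-timepoint denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import N_VARIANTS, PoolCountTable, all_variants, variant_index

DEFAULT_REFERENCE = "AAAAAG"
DEFAULT_PSEUDOCOUNT = 0.5

FLAG_OK = "ok"
FLAG_CENSORED = "censored_low"
FLAG_UNOBSERVED = "unobserved_t0"


def fraction_unreacted(
    counts_t0: np.ndarray,
    counts_f: np.ndarray,
    f: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-variant fraction remaining, F_i = (1-f) * p_i(f) / p_i(0).

    A pseudocount (default 0.5, Anscombe-style) is added to every cell before
    forming proportions so that zero-count variants stay finite.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    c0 = np.asarray(counts_t0, dtype=float) + pseudocount
    cf = np.asarray(counts_f, dtype=float) + pseudocount
    p0 = c0 / c0.sum()
    pf = cf / cf.sum()
    return (1.0 - f) * pf / p0


def krel_single_pair(
    counts_t0: np.ndarray,
    counts_f: np.ndarray,
    f: float,
    reference: str = DEFAULT_REFERENCE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ref_index: int | None = None,
) -> np.ndarray:
    """k_rel from a single (t0, f) sample pair: ln F_i / ln F_ref.

    The directly calibrated single-timepoint form; the reference must show
    depletion (F_ref < 1) for the ratio to be meaningful.
    """
    F = fraction_unreacted(counts_t0, counts_f, f, pseudocount)
    idx = variant_index(reference) if ref_index is None else ref_index
    F_ref = F[idx]
    if F_ref >= 1.0:
        raise ValueError("reference variant shows no depletion (F_ref >= 1)")
    return np.log(F) / np.log(F_ref)


@dataclass
class RelRateTable:
    """Per-variant relative rate constants calibrated to a reference leader.

    `data` columns: variant (index), k_rel, se_ln (standard error of
    ln k_rel), n_obs (timepoint x replicate estimates combined), flag.
    Flagged variants are retained, never dropped.
    """

    data: pd.DataFrame
    reference: str = DEFAULT_REFERENCE
    per_timepoint: pd.DataFrame | None = None
    per_timepoint_se: pd.DataFrame | None = None

    @property
    def k_rel(self) -> pd.Series:
        return self.data["k_rel"]

    def calibrate(self) -> "RelRateTable":
        """Rescale so the reference variant's k_rel is exactly 1 (idempotent)."""
        ref = float(self.data.loc[self.reference, "k_rel"])
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError("reference variant has no positive k_rel")
        out = self.data.copy()
        out["k_rel"] = out["k_rel"] / ref
        return RelRateTable(data=out, reference=self.reference,
                            per_timepoint=self.per_timepoint,
                            per_timepoint_se=self.per_timepoint_se)

    def to_csv(self, path: str | Path) -> None:
        self.data.rename_axis("variant").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, reference: str = DEFAULT_REFERENCE) -> "RelRateTable":
        data = pd.read_csv(path, index_col="variant")
        return cls(data=data, reference=reference)


def _single_timepoint_estimate(
    counts_t0: np.ndarray,
    counts_f: np.ndarray,
    f: float,
    pseudocount: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ln of pool-scaled rate, its variance, censored mask) for one (t0, f) pair.

    The returned values are ln(k_i / k_bar) where k_bar is the pool-average
    rate under start weights; the common offset is removed by the final
    reference calibration.
    """
    F = fraction_unreacted(counts_t0, counts_f, f, pseudocount)
    total_f = float(np.asarray(counts_f).sum())
    cap = 1.0 - 1.0 / (2.0 * total_f)  # half a read of apparent depletion
    censored = F >= 1.0
    F = np.minimum(F, cap)
    c0 = np.asarray(counts_t0, dtype=float) + pseudocount
    p0 = c0 / c0.sum()
    lF = np.log(F)
    s = -float(np.dot(p0, lF))  # pool log-depletion, proportional to exposure
    if s <= 0:
        raise ValueError("pool shows no net depletion; check f metadata")
    ln_krel = np.log(-lF) - math.log(s)

    # counting variance: var(ln p) ~ 1/count with pseudocounts, both samples;
    # the pool term s aggregates the full depth and adds nothing material
    cf = np.asarray(counts_f, dtype=float) + pseudocount
    var_lnF = 1.0 / c0 + 1.0 / cf
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln_krel = var_lnF / lF**2
    var_ln_krel = np.where(np.isfinite(var_ln_krel), var_ln_krel, np.inf)
    return ln_krel, var_ln_krel, censored


def krel_from_counts(
    table: PoolCountTable,
    reference: str = DEFAULT_REFERENCE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RelRateTable:
    """Estimate k_rel for every variant from a pool count table.

    Each replicate's f=0 sample anchors that replicate's timepoints; per
    (replicate, f) estimates of ln k_rel are combined by inverse-variance
    weighting and the result calibrated so the reference leader reads 1.
    """
    ref_idx = variant_index(reference)
    variants = all_variants()
    estimates, variances, rows = [], [], []
    n_censored_obs = np.zeros(N_VARIANTS, dtype=int)
    unobserved = np.zeros(N_VARIANTS, dtype=bool)

    for rep, grp in table.samples.groupby("replicate"):
        t0_sample = grp.loc[grp["f"] == 0, "sample"].iloc[0]
        c0 = table.counts[t0_sample].to_numpy()
        if c0[ref_idx] == 0:
            raise ValueError(f"reference variant unobserved at t=0 in {rep!r}")
        unobserved |= c0 == 0
        for _, row in grp[grp["f"] > 0].iterrows():
            cf = table.counts[row["sample"]].to_numpy()
            ln_k, var_k, censored = _single_timepoint_estimate(
                c0, cf, float(row["f"]), pseudocount
            )
            # censored estimates carry no usable rate information; keep them
            # out of the weighted mean but remember the tally
            var_k = np.where(censored, np.inf, var_k)
            n_censored_obs += censored
            estimates.append(ln_k)
            variances.append(var_k)
            rows.append({"replicate": rep, "f": float(row["f"]), "sample": row["sample"]})

    if not estimates:
        raise ValueError("count table has no f > 0 samples")

    E = np.vstack(estimates)  # (n_obs, 4096)
    V = np.vstack(variances)
    W = 1.0 / V
    usable = np.isfinite(W) & (W > 0)
    W = np.where(usable, W, 0.0)
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_mean = (W * np.where(usable, E, 0.0)).sum(axis=0) / wsum
        se_ln = np.sqrt(1.0 / wsum)
    # fully censored variants: fall back to the (censoring-bound) estimates
    all_censored = wsum == 0
    if all_censored.any():
        ln_mean = np.where(all_censored, E.mean(axis=0), ln_mean)
        se_ln = np.where(all_censored, np.inf, se_ln)

    if all_censored[ref_idx]:
        raise ValueError(
            "reference variant shows no depletion in any sample pair; "
            "calibration is impossible — check sample pairing and f metadata"
        )

    # a variant is censored-low only when no sample pair shows depletion, so
    # its combined value rests entirely on the censoring bound; individual
    # censored observations merely drop out of the weighted mean
    flags = np.full(N_VARIANTS, FLAG_OK, dtype=object)
    flags[all_censored] = FLAG_CENSORED
    flags[unobserved] = FLAG_UNOBSERVED

    # the reference calibration is itself an estimate; its uncertainty is a
    # common term on every other variant's ln k_rel
    se_ln = np.sqrt(se_ln**2 + se_ln[ref_idx] ** 2)
    se_ln[ref_idx] = 0.0

    data = pd.DataFrame(
        {
            "k_rel": np.exp(ln_mean),
            "se_ln": se_ln,
            "n_obs": usable.sum(axis=0),
            "n_censored_obs": n_censored_obs,
            "flag": flags,
        },
        index=pd.Index(variants, name="variant"),
    )
    tp_cols = [f"{r['replicate']}_f{r['f']:g}" for r in rows]
    idx = pd.Index(variants, name="variant")
    per_tp = pd.DataFrame(E.T, index=idx, columns=tp_cols)
    per_tp_se = pd.DataFrame(np.sqrt(V).T, index=idx, columns=tp_cols)
    result = RelRateTable(data=data, reference=reference, per_timepoint=per_tp,
                          per_timepoint_se=per_tp_se)
    return result.calibrate()


def rate_distribution(
    table: RelRateTable,
    bins: int = 40,
    subsets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Log-spaced histogram of k_rel, with optional variant-subset overlays."""
    k = table.k_rel.to_numpy()
    k = k[np.isfinite(k) & (k > 0)]
    lo, hi = k.min(), k.max()
    if lo == hi:
        edges = np.array([lo / 1.001, hi * 1.001])
    else:
        edges = np.logspace(np.log10(lo) - 1e-9, np.log10(hi) + 1e-9, bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    out = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    if subsets:
        for name, variants in subsets.items():
            sub = table.k_rel.loc[variants].to_numpy()
            sub = sub[np.isfinite(sub) & (sub > 0)]
            out[name], _ = np.histogram(sub, bins=edges)
    return out


def top_fraction(table: RelRateTable, q: float = 0.01) -> list[str]:
    """The ceil(q*N) variants with the largest k_rel; ties break by pool index."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    n_top = math.ceil(q * len(table.data))
    order = sorted(
        table.data.index,
        key=lambda v: (-table.data.loc[v, "k_rel"], variant_index(v)),
    )
    return order[:n_top]


def dinucleotide_subset(n2: str, n1: str) -> list[str]:
    """All variants with the given bases at N(-2) and N(-1)."""
    return [v for v in all_variants() if v[4] == n2 and v[5] == n1]
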