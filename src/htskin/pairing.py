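"""Pairing potential between the 5'-leader and the 3' RCCA tail.

Leader nucleotides just 5' of the RNase P cleavage site can pair with the
single-stranded RCCA at the tRNA 3' end, extending the acceptor stem and
inhibiting the conversion of the initial enzyme-substrate complex (ES) to the
catalytically committed state (ES*). The scorer here computes the maximum
number of base pairs an antiparallel duplex can form between a leader window
(default N(-2)N(-1), configurable up to N(-4)) and the tail, allowing
Watson-Crick (A:U, G:C) and wobble (G:U) pairs and unpaired bulges on either
strand, by a non-crossing matching dynamic program. No structural register is
assumed and no thermodynamics is scored — the quantity is pairing potential,
a pair count.

Variants whose window reaches a pair-count threshold (default two pairs) are
classified as pairing anti-determinants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .krel import RelRateTable
from .seqio import POSITIONS, all_variants, normalize_sequence

#: Default 3' tail, 5'->3'. R = A for the methionine substrate; use GCCA for R = G.
DEFAULT_TAIL = "ACCA"

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


def pair_type(a: str, b: str) -> str:
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _WOBBLE:
        return "wobble"
    raise ValueError(f"{a}:{b} is not a permitted pair")


@dataclass
class DuplexResult:
    """Maximum-cardinality pairing between a leader window and the tail.

    `trace` lists (leader_pos, tail_pos) index pairs into the 5'->3' strings;
    ties in the DP are resolved toward pairs closest to the cleavage site
    (the 3' end of the leader window).
    """

    max_pairs: int
    trace: list[tuple[int, int]]
    pair_types: list[str]
    leader: str
    tail: str


def max_duplex_pairs(leader_window: str, tail: str = DEFAULT_TAIL) -> DuplexResult:
    """Most base pairs an antiparallel leader/tail duplex can form.

    Both strands are given 5'->3'; antiparallel geometry means the leader
    read 5'->3' pairs monotonically against the tail read 3'->5', which
    reduces the problem to a longest-common-subsequence-style DP under the
    pairing predicate, with skips (bulges) free.
    """
    leader = normalize_sequence(leader_window) if leader_window else ""
    tail_n = normalize_sequence(tail) if tail else ""
    rtail = tail_n[::-1]
    n, m = len(leader), len(rtail)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(dp[i - 1][j], dp[i][j - 1])
            if can_pair(leader[i - 1], rtail[j - 1]):
                best = max(best, dp[i - 1][j - 1] + 1)
            dp[i][j] = best
    # traceback from the 3' end of the leader, pairing first on ties so the
    # reported trace sits as close to the cleavage site as possible
    trace: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if can_pair(leader[i - 1], rtail[j - 1]) and dp[i][j] == dp[i - 1][j - 1] + 1:
            trace.append((i - 1, m - j))  # map back to 5'->3' tail index
            i, j = i - 1, j - 1
        elif dp[i][j] == dp[i - 1][j]:
            i -= 1
        else:
            j -= 1
    trace.reverse()
    types = [pair_type(leader[li], tail_n[tj]) for li, tj in trace]
    return DuplexResult(max_pairs=int(dp[n][m]), trace=trace, pair_types=types,
                        leader=leader, tail=tail_n)


def classify_antideterminant(
    variant: str,
    threshold: int = 2,
    window: int = 2,
    tail: str = DEFAULT_TAIL,
) -> tuple[bool, int]:
    """Is the leader a 3'-RCCA pairing anti-determinant?

    Scores the cleavage-proximal `window` nucleotides (the last `window`
    characters of the 5'->3' leader, i.e. N(-window)..N(-1)) against the tail
    and compares the pair count to the threshold.
    """
    seq = normalize_sequence(variant)
    if window > len(seq):
        raise ValueError(f"window {window} exceeds leader length {len(seq)}")
    sub = seq[len(seq) - window:] if window > 0 else ""
    result = max_duplex_pairs(sub, tail)
    return result.max_pairs >= threshold, result.max_pairs


def subset_compare(
    table: RelRateTable,
    position: int = -2,
    base_from: str = "A",
    base_to: str = "G",
    fixed: Mapping[int, str] | None = None,
    stratify_by: int = -1,
) -> pd.DataFrame:
    """Paired k_rel comparison for a single-base substitution across backgrounds.

    For every sequence background satisfying the `fixed` position constraints,
    pairs the variant carrying `base_from` at `position` with its `base_to`
    counterpart, stratified by the base at `stratify_by`. Returns one row per
    background with both k_rel values and their ratio.
    """
    fixed = dict(fixed or {})
    pos_idx = POSITIONS.index(position)
    strat_idx = POSITIONS.index(stratify_by)
    rows = []
    for v in all_variants():
        if v[pos_idx] != base_from:
            continue
        if any(v[POSITIONS.index(p)] != b for p, b in fixed.items()):
            continue
        partner = v[:pos_idx] + base_to + v[pos_idx + 1:]
        rows.append({
            "background": v[:pos_idx] + "." + v[pos_idx + 1:],
            "stratum": v[strat_idx],
            f"k_rel_{base_from}": float(table.k_rel.loc[v]),
            f"k_rel_{base_to}": float(table.k_rel.loc[partner]),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("fixed-position constraints leave an empty subset")
    out["fold_change"] = out[f"k_rel_{base_to}"] / out[f"k_rel_{base_from}"]
    return out


def subset_fold_summary(compare: pd.DataFrame) -> pd.Series:
    """Median fold change per N(stratify) stratum from a subset_compare table."""
    return compare.groupby("stratum")["fold_change"].median()


def census_dinucleotides(
    leaders: Mapping[str, str] | Iterable[str],
    threshold: int = 2,
    tail: str = DEFAULT_TAIL,
) -> pd.DataFrame:
    """N(-2)N(-1) dinucleotide census of genomic ptRNA leader sequences.

    Counts each observed cleavage-proximal dinucleotide and classifies it by
    pairing potential with the tail. Sequences shorter than two nucleotides
    are skipped (tallied in the attrs). Input leaders are 5'->3'.
    """
    if isinstance(leaders, Mapping):
        seqs = list(leaders.values())
    else:
        seqs = list(leaders)
    counts: dict[str, int] = {}
    skipped = 0
    for s in seqs:
        s = normalize_sequence(s)
        if len(s) < 2:
            skipped += 1
            continue
        dinuc = s[-2:]  # N(-2)N(-1)
        counts[dinuc] = counts.get(dinuc, 0) + 1
    rows = []
    for dinuc, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        is_anti, pairs = classify_antideterminant(dinuc, threshold=threshold,
                                                 window=2, tail=tail)
        rows.append({"dinucleotide": dinuc, "count": n, "max_pairs": pairs,
                     "antideterminant": is_anti})
    out = pd.DataFrame(rows, columns=["dinucleotide", "count", "max_pairs",
                                      "antideterminant"])
    out.attrs["n_sequences"] = len(seqs) - skipped
    out.attrs["n_skipped"] = skipped
    return out
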