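"""Sequence and tabular I/O for HTS-Kin experiments.

The randomized region of the substrate pool is a hexamer occupying 5'-leader
positions N(-6)..N(-1), where N(-1) abuts the RNase P cleavage site. Reads are
amplicon-style: a fixed 5' constant region, the hexamer, then a fixed 3'
constant region. This module extracts the hexamer from reads, normalizes the
alphabet (DNA T -> RNA U), and aggregates per-variant counts into the dense
4096-row tables the kinetics layer consumes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

#: Leader positions of the randomized hexamer, 5' -> 3'. N(-1) is adjacent to
#: the cleavage site.
POSITIONS: tuple[int, ...] = (-6, -5, -4, -3, -2, -1)

LEADER_LENGTH = 6
N_VARIANTS = 4 ** LEADER_LENGTH  # 4096

# T7 transcription template for the randomized ptRNA(met) pool: promoter and
# 5' distal stem-loop region, then NNNNNN, then the start of the tRNA body.
CONSTRUCT_UPSTREAM = "TAATACGACTCACTATAGCATGCACGAAAGTGCGTGCTATGAA"
CONSTRUCT_DOWNSTREAM = "GGCTACGTAGCTCAGTTGG"


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; raise on foreign characters."""
    s = seq.upper().replace("T", "U")
    if any(b not in _BASE_INDEX for b in s):
        raise ValueError(f"non-ACGU/T character in sequence {seq!r}")
    return s


def variant_index(sequence: str) -> int:
    """Lexicographic rank of a hexamer (A<C<G<U), AAAAAA -> 0, UUUUUU -> 4095."""
    s = normalize_sequence(sequence)
    if len(s) != LEADER_LENGTH:
        raise ValueError(f"leader variant must be {LEADER_LENGTH} nt, got {s!r}")
    idx = 0
    for b in s:
        idx = idx * 4 + _BASE_INDEX[b]
    return idx


def index_to_variant(index: int) -> str:
    if not 0 <= index < N_VARIANTS:
        raise ValueError(f"variant index out of range: {index}")
    out = []
    for _ in range(LEADER_LENGTH):
        out.append(RNA_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def all_variants() -> list[str]:
    """All 4096 hexamers in lexicographic order."""
    return [index_to_variant(i) for i in range(N_VARIANTS)]


@dataclass(frozen=True)
class LeaderVariant:
    """A single randomized 5'-leader hexamer N(-6)..N(-1)."""

    sequence: str
    index: int

    @classmethod
    def from_sequence(cls, sequence: str) -> "LeaderVariant":
        s = normalize_sequence(sequence)
        return cls(sequence=s, index=variant_index(s))

    def base_at(self, position: int) -> str:
        """Base at leader position (-6..-1)."""
        return self.sequence[POSITIONS.index(position)]


@dataclass(frozen=True)
class AnchorConfig:
    """Constant flanks used to locate the randomized hexamer inside a read.

    Flanks are given in the read's alphabet (DNA or RNA, matched after T->U
    normalization). `max_mismatches` is a per-flank Hamming budget; indels are
    not tolerated (amplicon reads).
    """

    upstream: str = CONSTRUCT_UPSTREAM[-8:]
    downstream: str = CONSTRUCT_DOWNSTREAM[:8]
    max_mismatches: int = 1

    def __post_init__(self):
        object.__setattr__(self, "upstream", normalize_sequence(self.upstream))
        object.__setattr__(self, "downstream", normalize_sequence(self.downstream))


def _find_with_mismatches(haystack: str, needle: str, budget: int) -> int:
    """Leftmost start of `needle` in `haystack` within a Hamming budget, or -1."""
    pos = haystack.find(needle)
    if pos >= 0 or budget == 0:
        return pos
    n, m = len(haystack), len(needle)
    for start in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[start:start + m], needle):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return start
    return -1


def extract_variant(read: str, anchors: AnchorConfig | None = None) -> str | None:
    """Pull the 6-nt randomized region out of a read, or None on no-match.

    The upstream flank is located first (exact match preferred, then Hamming
    within budget); the hexamer is the 6 nt that follow; the downstream flank
    must then match at the expected offset within the same budget.
    """
    anchors = anchors or AnchorConfig()
    if not read:
        return None
    try:
        r = normalize_sequence(read)
    except ValueError:
        return None
    up = _find_with_mismatches(r, anchors.upstream, anchors.max_mismatches)
    if up < 0:
        return None
    start = up + len(anchors.upstream)
    end = start + LEADER_LENGTH
    down = anchors.downstream
    if end + len(down) > len(r):
        return None
    mism = sum(a != b for a, b in zip(r[end:end + len(down)], down))
    if mism > anchors.max_mismatches:
        return None
    return r[start:end]


@dataclass
class PoolCountTable:
    """Dense per-variant read counts across samples.

    `counts` is a (4096, n_samples) integer frame indexed by variant sequence;
    `samples` carries one row per column with its replicate label and the
    fraction of total substrate reacted f (f = 0 marks the start-of-reaction
    reference sample of that replicate). All 4096 rows are always present so
    that any pseudocount policy downstream is explicit.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, replicate, f
    rejected: int = 0

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if list(self.counts.index) != all_variants():
            raise ValueError("count table must cover all 4096 variants in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"samples with zero accepted reads: {bad}")
        for rep, grp in self.samples.groupby("replicate"):
            if int((grp["f"] == 0).sum()) != 1:
                raise ValueError(
                    f"replicate {rep!r} must have exactly one f=0 reference sample"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.counts.rename_axis("variant")
            .reset_index()
            .melt(id_vars="variant", var_name="sample", value_name="count")
        )
        return tidy.merge(self.samples[["sample", "replicate", "f"]], on="sample")

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, rejected: int = 0) -> "PoolCountTable":
        counts = (
            tidy.pivot_table(index="variant", columns="sample", values="count",
                             aggfunc="sum", fill_value=0)
            .reindex(all_variants(), fill_value=0)
        )
        counts.columns.name = None
        samples = tidy[["sample", "replicate", "f"]].drop_duplicates("sample")
        counts = counts[[s for s in samples["sample"]]]
        return cls(counts=counts.astype(np.int64), samples=samples, rejected=rejected)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PoolCountTable":
        return cls.from_tidy(pd.read_csv(path))


def count_table(
    reads_per_sample: Mapping[str, Iterable[str]],
    sample_meta: pd.DataFrame,
    anchors: AnchorConfig | None = None,
) -> PoolCountTable:
    """Extract variants from raw reads and build the dense count table.

    `sample_meta` needs columns (sample, replicate, f). Reads failing
    extraction are tallied in the result's `rejected` field, never counted.
    """
    anchors = anchors or AnchorConfig()
    variants = all_variants()
    columns = {}
    rejected = 0
    for sample, reads in reads_per_sample.items():
        col = np.zeros(N_VARIANTS, dtype=np.int64)
        for read in reads:
            hexamer = extract_variant(read, anchors)
            if hexamer is None:
                rejected += 1
            else:
                col[variant_index(hexamer)] += 1
        columns[sample] = col
    counts = pd.DataFrame(columns, index=variants)
    meta = sample_meta[["sample", "replicate", "f"]].copy()
    counts = counts[[s for s in meta["sample"]]]
    return PoolCountTable(counts=counts, samples=meta, rejected=rejected)


def _open_maybe_gzip(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a (possibly gzipped) FASTQ file."""
    with _open_maybe_gzip(path, "r") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(path: str | Path, reads: Sequence[str], quality: int = 40) -> None:
    """Write reads as 4-line FASTQ with uniform Phred qualities."""
    records = []
    for i, read in enumerate(reads):
        rec = SeqRecord(Seq(read), id=f"read{i}", description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(read)
        records.append(rec)
    with _open_maybe_gzip(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_leader_fasta(path: str | Path) -> dict[str, str]:
    """Read genomic ptRNA 5'-leader sequences (id -> U-normalized sequence)."""
    with _open_maybe_gzip(path, "r") as fh:
        return {rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}
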