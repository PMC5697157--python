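"""Small RNA read preprocessing: adapter/quality cleaning, collapsing to
unique tags, length distributions, ncRNA contaminant removal and size
selection.

The cascade mirrors a standard small RNA library workflow: raw reads are
cleaned (adapter trim, minimum length 15 nt, ambiguous-base and quality
rules), collapsed to unique tags, profiled by length, purged of
rRNA/tRNA/snoRNA/snRNA contaminants against a user-supplied reference, and
finally restricted to the 17-25 nt window used for miRNA prediction.  The
length distribution is computed *before* size selection so the full 15-30 nt
profile is reported.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seq import revcomp


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length != sequence length")


@dataclass(frozen=True)
class UniqueTag:
    sequence: str
    count: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def shannon_entropy(seq: str) -> float:
    """Per-nucleotide Shannon entropy in bits (dust-style complexity score)."""
    n = len(seq)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(seq).values()
    ) if n else 0.0


def clean_reads(
    reads: list[ReadRecord],
    adapter: str | None = None,
    min_len: int = 15,
    max_n: int = 0,
    min_mean_phred: float = 20.0,
    low_complexity_entropy: float | None = None,
) -> list[ReadRecord]:
    """Trim the 3' adapter and drop short / ambiguous / low-quality reads.

    The adapter is trimmed at its leftmost match of >= 8 exact bases.
    "Low quality" is operationalised as mean Phred < ``min_mean_phred`` when
    qualities exist; FASTA input skips that rule.  The entropy dust filter is
    off by default.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if adapter is not None and len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt for reliable trimming")
    probe = adapter[:8].upper() if adapter else None
    kept = []
    for r in reads:
        seq, qual = r.sequence, r.quality
        if probe:
            idx = seq.find(probe)
            if idx >= 0:
                seq = seq[:idx]
                qual = qual[:idx] if qual is not None else None
        if len(seq) < min_len:
            continue
        if seq.count("N") > max_n:
            continue
        if qual and sum(qual) / len(qual) < min_mean_phred:
            continue
        if low_complexity_entropy is not None and shannon_entropy(seq) < low_complexity_entropy:
            continue
        kept.append(ReadRecord(r.read_id, seq, qual))
    return kept


def collapse(reads: list[ReadRecord]) -> list[UniqueTag]:
    """One tag per distinct sequence; deterministic order (descending count,
    then lexicographic)."""
    counts = Counter(r.sequence for r in reads)
    return [
        UniqueTag(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(tags: list[UniqueTag]) -> pd.DataFrame:
    """Per-length read-weighted and unique-tag tallies with percentages."""
    total_reads = Counter()
    unique_tags = Counter()
    for t in tags:
        total_reads[t.length] += t.count
        unique_tags[t.length] += 1
    n_reads = sum(total_reads.values())
    n_tags = sum(unique_tags.values())
    rows = [
        {
            "length": L,
            "total_reads": total_reads[L],
            "unique_tags": unique_tags[L],
            "total_percent": 100.0 * total_reads[L] / n_reads if n_reads else 0.0,
            "unique_percent": 100.0 * unique_tags[L] / n_tags if n_tags else 0.0,
        }
        for L in sorted(total_reads)
    ]
    return pd.DataFrame(rows, columns=[
        "length", "total_reads", "unique_tags", "total_percent", "unique_percent",
    ])


def _matches_within(tag: str, ref: str, max_mismatch: int) -> bool:
    n, m = len(tag), len(ref)
    if n > m:
        return False
    if max_mismatch == 0:
        return tag in ref
    for start in range(m - n + 1):
        mm = 0
        for a, b in zip(tag, ref[start:start + n]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def filter_ncrna(
    tags: list[UniqueTag],
    reference: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[list[UniqueTag], list[UniqueTag]]:
    """Partition tags into (kept, removed): a tag is removed iff it occurs as
    a substring of any contaminant record on either strand with at most
    ``max_mismatch`` substitutions."""
    if not reference:
        raise ValueError("contaminant reference is empty")
    refs = []
    for seq in reference.values():
        refs.append(seq)
        refs.append(revcomp(seq))
    kept, removed = [], []
    for t in tags:
        if any(_matches_within(t.sequence, r, max_mismatch) for r in refs):
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed


def size_select(tags: list[UniqueTag], lo: int = 17, hi: int = 25) -> list[UniqueTag]:
    """Keep tags with lo <= length <= hi (both inclusive)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return [t for t in tags if lo <= t.length <= hi]


def unique_read_percent(n_unique: int, n_raw: int) -> float:
    """Percentage of unique (surviving) reads among raw reads, 2 decimals."""
    if n_raw <= 0:
        raise ValueError("raw read count must be positive")
    return round(100.0 * n_unique / n_raw, 2)
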