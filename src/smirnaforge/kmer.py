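"""k-mer genome survey: multiplicity histogram, coverage-peak location and
genome-size estimation.

Genome size is estimated as total k-mer count divided by the depth of the
main peak of the k-mer multiplicity spectrum -- the standard survey formula
for short-read data (k = 17 by default).  Counting is strand-naive by
default; canonical (strand-merged) counting is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seq import revcomp


@dataclass
class KmerHistogram:
    k: int
    total_kmer_count: int
    freq: dict[int, int] = field(default_factory=dict)  # depth -> distinct k-mers

    def __post_init__(self):
        mass = sum(d * c for d, c in self.freq.items())
        if mass != self.total_kmer_count:
            raise ValueError(
                f"histogram mass {mass} != total k-mer count {self.total_kmer_count}"
            )
        if any(d < 1 or c < 0 for d, c in self.freq.items()):
            raise ValueError("negative or zero-depth histogram entries")


@dataclass
class GenomeSurveyResult:
    peak_depth: int
    genome_size_bp: float
    coverage_x: float | None = None


def count_kmers(
    sequences: list[str] | dict[str, str],
    k: int = 17,
    canonical: bool = False,
) -> KmerHistogram:
    """Count every N-free window of length k on the given strand.

    ``canonical=True`` merges each k-mer with its reverse complement
    (lexicographic minimum), halving strand redundancy of real WGS reads.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    counts: Counter[str] = Counter()
    for seq in seqs:
        seq = seq.upper()
        n = len(seq)
        # restart the scan after each N to skip windows containing it
        start = 0
        while start <= n - k:
            bad = seq.find("N", start, start + k)
            if bad >= 0:
                start = bad + 1
                continue
            kmer = seq[start:start + k]
            if canonical:
                rc = revcomp(kmer)
                kmer = min(kmer, rc)
            counts[kmer] += 1
            start += 1
    hist: Counter[int] = Counter(counts.values())
    total = sum(counts.values())
    return KmerHistogram(k=k, total_kmer_count=total, freq=dict(hist))


def find_peak(hist: KmerHistogram, min_depth: int = 4) -> int:
    """Depth of the main coverage peak: argmax of distinct-k-mer frequency
    over depths >= min_depth (which excludes the sequencing-error peak at
    depth 1-3); ties broken toward smaller depth."""
    candidates = {d: c for d, c in hist.freq.items() if d >= min_depth and c > 0}
    if not candidates:
        raise ValueError("no coverage peak: all histogram mass below min_depth")
    best = max(candidates.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def estimate_genome_size(hist: KmerHistogram | int, peak_depth: int) -> float:
    """Genome size (bp) = total k-mer count / peak depth.

    Accepts a KmerHistogram or a raw total k-mer count.
    """
    if peak_depth < 1:
        raise ValueError("peak depth must be >= 1")
    total = hist.total_kmer_count if isinstance(hist, KmerHistogram) else int(hist)
    return total / peak_depth


def genome_size_gb_truncated(genome_size_bp: float, decimals: int = 2) -> float:
    """Genome size in Gb truncated (not rounded) to ``decimals`` places."""
    scale = 10 ** decimals
    return int(genome_size_bp / 1e9 * scale) / scale


def coverage(total_sequenced_bases: float, genome_size_bp: float) -> float:
    """Sequencing coverage as the plain ratio bases / genome size."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return total_sequenced_bases / genome_size_bp
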