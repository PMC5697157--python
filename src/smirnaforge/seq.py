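"""Small sequence helpers shared across the pipeline.

Sequences live on disk as DNA (T, per FASTA/FASTQ convention) and are
normalised at module boundaries: folding and duplex scoring work on RNA,
everything else on upper-case DNA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    s = to_dna(seq)
    if not s:
        return 0.0
    return 100.0 * sum(c in "GC" for c in s) / len(s)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: upper-case DNA sequence}, order-preserving."""
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, phred: int = 40) -> None:
    """Write reads with a constant Phred+33 quality."""
    recs = []
    for name, seq in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [phred] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def iter_reads(path: str | Path) -> Iterator[tuple[str, str, list[int] | None]]:
    """Yield (id, sequence, qualities or None) from FASTA or FASTQ."""
    path = str(path)
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(path, fmt):
        qual = rec.letter_annotations.get("phred_quality")
        yield rec.id, to_dna(str(rec.seq)), list(qual) if qual is not None else None
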