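"""Synthetic data generator: genomes with planted miRNA hairpins, small RNA
reads, known-miRNA references, contaminants and expression tables.

Everything downstream of sequencing is testable against the truth table this
module emits.  The defaults emulate the study conditions the pipeline is
built for: a small RNA library whose read-length distribution peaks at 24 nt
with a secondary 21-nt mode, hairpin precursors embedded in genome-survey
scaffolds, ncRNA contaminants, and expression tables with planted fold
changes and one miRNA-target pair with anti-correlated profiles.

Sequences are DNA (T) on disk and in memory here; RNA conversion happens at
the folding/duplex boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq import revcomp, write_fasta, write_fastq

BASES = np.array(list("ACGT"))

# Conserved plant miRNA family names used for synthetic "foreign species"
# references; cycled when more loci are flagged conserved than names exist.
FAMILY_POOL = [
    "miR156", "miR159", "miR160", "miR164", "miR166", "miR167", "miR169",
    "miR171", "miR172", "miR319", "miR390", "miR393", "miR395", "miR396",
    "miR398", "miR408", "miR477", "miR482", "miR535", "miR858",
]

# Joint weights for (5' shift, 3' shift) end jitter relative to the planted
# mature arm.  With a 24-nt mature these give an aggregate read-length mode
# at 24 nt and a secondary mode at 21 nt.
JITTER_WEIGHTS: dict[tuple[int, int], float] = {
    (0, 0): 0.50, (-1, -1): 0.02,          # 24 nt
    (2, -1): 0.12, (1, -2): 0.07,          # 21 nt
    (1, 0): 0.07, (0, -1): 0.06,           # 23 nt
    (2, 0): 0.05, (0, -2): 0.05,           # 22 nt
    (-1, 0): 0.02, (0, 1): 0.02,           # 25 nt
    (-2, 0): 0.01, (0, 2): 0.01,           # 26 nt (removed later by size select)
}


@dataclass
class TruthRecord:
    """Ground truth for one planted hairpin locus."""

    locus_id: str
    scaffold_id: str
    precursor_start: int  # 1-based inclusive, forward strand
    precursor_end: int
    mature_seq: str       # DNA alphabet; exact subsequence of the precursor
    arm: str              # "5p" or "3p"
    mature_start: int     # genomic, 1-based inclusive
    mature_end: int
    is_conserved: bool = False
    family: str | None = None
    planted_read_count: int = 0
    precursor_seq: str = ""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _perturb_arm(arm5: str, rng: np.random.Generator, wc_fraction: float) -> str:
    """Reverse complement of the 5' arm with a (1 - wc_fraction) share of
    positions turned into G:U-compatible pairs or mismatches."""
    partner = list(revcomp(arm5))
    n = len(arm5)
    n_mut = int(round((1.0 - wc_fraction) * n))
    # partner index j pairs with arm5 index n-1-j
    for j in rng.choice(n, size=n_mut, replace=False):
        b5 = arm5[n - 1 - j]
        if b5 == "G":
            partner[j] = "T"  # G:U wobble
        elif b5 == "T":
            partner[j] = "G"  # U:G wobble
        else:
            choices = [c for c in "ACGT" if c not in (partner[j],)]
            partner[j] = str(rng.choice(choices))
    return "".join(partner)


def make_genome(
    seed: int,
    n_scaffolds: int = 4,
    scaffold_length: int = 250_000,
    n_hairpins: int = 20,
    stem_len: int = 24,
    loop_len: int = 8,
    wc_fraction: float = 0.90,
    min_gap: int = 50,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Random scaffolds with non-overlapping planted hairpin precursors.

    Each precursor is ``arm + loop + perturbed-revcomp(arm)``; the mature
    sequence is the full arm on a randomly chosen side.  Background is
    i.i.d. uniform ACGT, so no competing long hairpins arise at desk scale.
    """
    if stem_len < 20:
        raise ValueError("stem_len must be >= 20")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    prec_len = 2 * stem_len + loop_len
    if prec_len > scaffold_length:
        raise ValueError("precursor longer than scaffold")

    rng = np.random.default_rng(seed)
    scaffolds = {
        f"scaffold{i + 1}": list(_random_seq(rng, scaffold_length))
        for i in range(n_scaffolds)
    }
    names = list(scaffolds)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    truth: list[TruthRecord] = []

    for h in range(n_hairpins):
        placed = False
        for _ in range(1000):
            sid = names[int(rng.integers(0, n_scaffolds))]
            start = int(rng.integers(0, scaffold_length - prec_len + 1))  # 0-based
            span = (start - min_gap, start + prec_len + min_gap)
            if any(not (span[1] <= a or span[0] >= b) for a, b in occupied[sid]):
                continue
            arm5 = _random_seq(rng, stem_len)
            arm3 = _perturb_arm(arm5, rng, wc_fraction)
            loop = _random_seq(rng, loop_len)
            precursor = arm5 + loop + arm3
            scaffolds[sid][start:start + prec_len] = list(precursor)
            occupied[sid].append((start, start + prec_len))
            arm = "5p" if rng.random() < 0.5 else "3p"
            if arm == "5p":
                m_start, m_end = start + 1, start + stem_len
                mature = arm5
            else:
                m_start, m_end = start + prec_len - stem_len + 1, start + prec_len
                mature = arm3
            truth.append(TruthRecord(
                locus_id=f"locus{h + 1:03d}",
                scaffold_id=sid,
                precursor_start=start + 1,
                precursor_end=start + prec_len,
                mature_seq=mature,
                arm=arm,
                mature_start=m_start,
                mature_end=m_end,
                precursor_seq=precursor,
            ))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"infeasible packing: could not place hairpin {h + 1} of "
                f"{n_hairpins} without overlap"
            )
    return {k: "".join(v) for k, v in scaffolds.items()}, truth


def make_contaminants(seed: int, n_records: int = 8, length: int = 150) -> list[tuple[str, str]]:
    """Synthetic ncRNA contaminant reference (random sequences with
    rRNA/tRNA/snoRNA/snRNA-style names)."""
    rng = np.random.default_rng(seed)
    kinds = ["rRNA", "tRNA", "snoRNA", "snRNA"]
    return [
        (f"{kinds[i % len(kinds)]}_{i // len(kinds) + 1}", _random_seq(rng, length))
        for i in range(n_records)
    ]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < error_rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def make_reads(
    truth: list[TruthRecord],
    scaffolds: dict[str, str],
    depth_per_locus: int,
    contaminant_fraction: float = 0.0,
    contaminants: list[tuple[str, str]] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    jitter: bool = True,
) -> list[tuple[str, str]]:
    """Sample reads from mature arms (with end jitter drawn from
    JITTER_WEIGHTS) plus contaminant reads; substitution errors applied at
    ``error_rate`` per base."""
    if contaminant_fraction > 0 and not contaminants:
        raise ValueError("contaminant reference required when contaminant_fraction > 0")
    rng = np.random.default_rng(seed)
    deltas = list(JITTER_WEIGHTS)
    weights = np.array([JITTER_WEIGHTS[d] for d in deltas])
    weights = weights / weights.sum()

    reads: list[tuple[str, str]] = []
    n_mature_target = depth_per_locus * len(truth)
    if contaminant_fraction >= 1.0:
        n_contam = max(n_mature_target, depth_per_locus)
        n_mature_target = 0
    elif contaminant_fraction > 0:
        n_contam = int(round(n_mature_target * contaminant_fraction / (1 - contaminant_fraction)))
    else:
        n_contam = 0

    if n_mature_target:
        for rec in truth:
            scaffold = scaffolds[rec.scaffold_id]
            rec.planted_read_count = depth_per_locus
            for _ in range(depth_per_locus):
                if jitter:
                    d5, d3 = deltas[int(rng.choice(len(deltas), p=weights))]
                else:
                    d5 = d3 = 0
                s = max(rec.mature_start - 1 + d5, 0)
                e = min(rec.mature_end + d3, len(scaffold))
                seq = scaffold[s:e]
                reads.append((rec.locus_id, _apply_errors(seq, rng, error_rate)))
    if n_contam:
        for _ in range(n_contam):
            name, cseq = contaminants[int(rng.integers(0, len(contaminants)))]
            rl = int(rng.integers(18, 27))
            start = int(rng.integers(0, max(len(cseq) - rl, 0) + 1))
            seq = _apply_errors(cseq[start:start + rl], rng, error_rate)
            reads.append((f"contam_{name}", seq))
    if not reads:
        warnings.warn("no reads generated (zero depth and no contaminants)")
        return []
    order = rng.permutation(len(reads))
    return [(f"read{i + 1}_{reads[j][0]}", reads[j][1]) for i, j in enumerate(order)]


def make_known_reference(
    truth: list[TruthRecord],
    n_conserved: int,
    max_divergence: int = 2,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Emit a miRBase-style mature reference for ``n_conserved`` planted loci.

    Each emitted "foreign species" sequence differs from the planted mature
    by 0..max_divergence substitutions; the header carries the family name
    (e.g. ``ath-miR166a``).  Marks those truth records conserved.
    """
    if n_conserved > len(truth):
        raise ValueError("n_conserved exceeds number of truth loci")
    if max_divergence > 3:
        warnings.warn("max_divergence > 3: homology stage will miss these by design")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    for i, rec in enumerate(truth[:n_conserved]):
        family = FAMILY_POOL[i % len(FAMILY_POOL)]
        variant = chr(ord("a") + i // len(FAMILY_POOL))
        rec.is_conserved = True
        rec.family = family
        seq = list(rec.mature_seq)
        n_sub = int(rng.integers(0, max_divergence + 1))
        for p in rng.choice(len(seq), size=n_sub, replace=False):
            seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
        records.append((f"ath-{family}{variant}", "".join(seq)))
    return records


def make_expression_tables(
    truth: list[TruthRecord],
    n_tissues: int,
    fold_changes: dict[str, list[float]],
    seed: int = 0,
    noise_cv: float = 0.0,
    background_mean: float = 50.0,
    background_sd: float = 5.0,
    base_signal: float = 500.0,
    base_ct: float = 26.0,
    control_ct: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Microarray spot-signal and qRT-PCR Ct tables with planted fold changes.

    A planted fold change f in tissue t shifts the miRNA Ct by -log2(f)
    against a constant internal control (U6).  One planted miRNA-target pair
    (the first locus vs ``target_of_<locus>``, controlled by GAPDH) carries
    exactly inverted fold changes, so the pair's log2 relative-expression
    profiles are anti-correlated (Pearson r = -1 at zero noise).
    """
    for locus, folds in fold_changes.items():
        if any(f <= 0 for f in folds):
            raise ValueError(f"fold changes must be strictly positive ({locus})")
        if len(folds) != n_tissues:
            raise ValueError(f"need one fold change per tissue for {locus}")
    rng = np.random.default_rng(seed)
    tissues = [f"tissue{i + 1}" for i in range(n_tissues)]

    # --- microarray: triplicate spots per probe, one channel per tissue
    spot_rows = []
    for rec in truth:
        folds = fold_changes.get(rec.locus_id, [1.0] * n_tissues)
        level = base_signal * max(rec.planted_read_count, 1) / 50.0
        for t, tissue in enumerate(tissues):
            signal = level * folds[t]
            reps = signal * (1.0 + noise_cv * rng.standard_normal(3)) + background_mean
            spot_rows.append({
                "probe_id": rec.locus_id, "tissue": tissue,
                "rep1": reps[0], "rep2": reps[1], "rep3": reps[2],
                "bg_mean": background_mean, "bg_sd": background_sd,
            })
    microarray = pd.DataFrame(spot_rows)

    # --- qRT-PCR Ct table
    ct_rows = []

    def _add(sample, gene, ct):
        for r in range(3):
            ct_rows.append({
                "sample": sample, "gene": gene, "replicate": r + 1,
                "ct": ct + noise_cv * rng.standard_normal(),
            })

    for t, tissue in enumerate(tissues):
        _add(tissue, "U6", control_ct)
        _add(tissue, "GAPDH", control_ct + 2.0)
        for rec in truth:
            folds = fold_changes.get(rec.locus_id, [1.0] * n_tissues)
            _add(tissue, rec.locus_id, base_ct - np.log2(folds[t]))
    if truth:
        pair = truth[0]
        folds = fold_changes.get(pair.locus_id, [1.0] * n_tissues)
        for t, tissue in enumerate(tissues):
            # inverted fold change => anti-correlated log2 profile
            _add(tissue, f"target_of_{pair.locus_id}", base_ct + np.log2(folds[t]))
    ct = pd.DataFrame(ct_rows)
    return microarray, ct


def make_wgs_reads(
    scaffolds: dict[str, str], depth: int, fragment_len: int = 1000, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniform-coverage genome-survey fragments: ``depth`` tiling passes, each
    with a random phase offset.  Long fragments keep the per-fragment k-mer
    loss (k-1 per fragment) small so genome-size estimates stay unbiased."""
    rng = np.random.default_rng(seed)
    reads = []
    i = 0
    for _ in range(depth):
        for sid, seq in scaffolds.items():
            phase = int(rng.integers(0, fragment_len))
            for start in range(phase, len(seq), fragment_len):
                frag = seq[start:start + fragment_len]
                if frag:
                    i += 1
                    reads.append((f"wgs{i}_{sid}", frag))
            if phase:
                i += 1
                reads.append((f"wgs{i}_{sid}", seq[:phase]))
    return reads


TRUTH_COLUMNS = ["locus_id", "scaffold_id", "start", "end", "arm",
                 "mature_seq", "is_conserved", "count"]


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"locus_id": r.locus_id, "scaffold_id": r.scaffold_id,
         "start": r.precursor_start, "end": r.precursor_end, "arm": r.arm,
         "mature_seq": r.mature_seq, "is_conserved": r.is_conserved,
         "count": r.planted_read_count}
        for r in truth
    ], columns=TRUTH_COLUMNS)


def simulate_bundle(
    out_dir: str | Path,
    seed: int,
    n_scaffolds: int = 4,
    scaffold_length: int = 250_000,
    n_hairpins: int = 20,
    depth_per_locus: int = 50,
    contaminant_fraction: float = 0.1,
    error_rate: float = 0.0,
    n_conserved: int | None = None,
    max_divergence: int = 2,
) -> dict[str, Path]:
    """Generate and write a full synthetic input bundle; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaffolds, truth = make_genome(
        seed, n_scaffolds=n_scaffolds, scaffold_length=scaffold_length,
        n_hairpins=n_hairpins,
    )
    contaminants = make_contaminants(seed + 1)
    if n_conserved is None:
        n_conserved = n_hairpins // 2
    known = make_known_reference(truth, n_conserved, max_divergence, seed + 2)
    reads = make_reads(
        truth, scaffolds, depth_per_locus, contaminant_fraction,
        contaminants, error_rate, seed + 3,
    )
    fold_changes = {truth[0].locus_id: [1.0, 8.0]} if truth else {}
    n_tissues = 2
    microarray, ct = make_expression_tables(truth, n_tissues, fold_changes, seed + 4)

    paths = {
        "scaffolds": out / "scaffolds.fa",
        "reads": out / "reads.fq",
        "contaminants": out / "contaminants.fa",
        "known": out / "known_mirnas.fa",
        "truth": out / "truth.tsv",
        "microarray": out / "microarray.tsv",
        "ct": out / "ct.tsv",
    }
    write_fasta(scaffolds.items(), paths["scaffolds"])
    write_fastq(reads, paths["reads"])
    write_fasta(contaminants, paths["contaminants"])
    write_fasta(known, paths["known"])
    truth_to_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    microarray.to_csv(paths["microarray"], sep="\t", index=False)
    ct.to_csv(paths["ct"], sep="\t", index=False)
    return paths
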