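"""Candidate pre-miRNA extraction, folding, structural metrics and the
twelve-criterion hairpin filter, plus group 1/2a/2b/3 classification.

A tag located on a scaffold/EST seeds two candidate windows (tag on the 5'
or the 3' arm).  Each window is folded at minimum free energy; the stem-loop
component containing the tag is excised and re-folded, and the resulting
hairpin is scored: MFE, AMFE = (|MFE|/length)*100, MFEI = AMFE/GC%, stem and
mature-region pairing tallies, bulge sizes.  Twelve criteria gate the call:

  c1  largest bulge in the stem <= 12 nt
  c2  >= 16 base pairs in the stem
  c3  hairpin length (stems + terminal loop) >= 50 nt
  c4  terminal loop <= 200 nt
  c5  <= 4 nt in any one bulge of the mature region
  c6  <= 2 nt of one-sided (biased) bulge in the mature region
  c7  <= 2 bulges in the mature region
  c8  <= 4 unpaired nt (errors) in the mature region
  c9  >= 12 base pairs in the mature region
  c10 >= 80% of the mature region inside the stem
  c11 MFE <= -12 kcal/mol
  c12 MFEI >= 0.7 (>= 0.4 when a predicted target exists)

MFEI >= 0.85 is additionally flagged as high confidence.  Folding defaults
to the ViennaRNA MFE engine behind a pluggable backend interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .seq import gc_percent, revcomp, to_rna

FoldBackend = Callable[[str], tuple[str, float]]

_vienna = None


def _vienna_fold(seq: str) -> tuple[str, float]:
    global _vienna
    if _vienna is None:
        import RNA as _vienna_mod
        _vienna = _vienna_mod
    structure, mfe = _vienna.fold(seq)
    return structure, float(mfe)


def fold(sequence: str, backend: FoldBackend | None = None) -> tuple[str, float]:
    """Single MFE secondary structure in dot-bracket form with its energy
    (kcal/mol).  Deterministic for a fixed backend."""
    rna = to_rna(sequence)
    if len(rna) < 10:
        raise ValueError("sequence too short to fold (< 10 nt)")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters after RNA normalization: {sorted(bad)}")
    return (backend or _vienna_fold)(rna)


def parse_structure(structure: str) -> list[int]:
    """Dot-bracket -> pair table: pt[i] = j (0-based) iff i pairs j, else -1."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced brackets: unmatched ')'")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced brackets: unmatched '('")
    return pt


@dataclass
class Hairpin:
    locus: tuple[str, int, int, str]  # (sequence_id, start, end, strand), 1-based
    precursor_seq: str                # DNA alphabet
    structure: str
    mfe_kcal_mol: float
    mature_start: int                 # 1-based inclusive on precursor
    mature_end: int
    arm: str                          # "5p" or "3p"

    def __post_init__(self):
        if len(self.structure) != len(self.precursor_seq):
            raise ValueError("structure length != precursor length")
        if not (1 <= self.mature_start <= self.mature_end <= len(self.precursor_seq)):
            raise ValueError("mature interval outside precursor")


@dataclass
class HairpinMetrics:
    length: int
    gc_percent: float
    mfe: float
    amfe: float
    mfei: float | None
    stem_pairs: int
    max_stem_bulge: int
    loop_length: int
    mature_pairs: int
    mature_max_bulge: int
    mature_max_asym_bulge: int
    mature_bulge_count: int
    mature_mismatch_nt: int
    mature_in_stem_fraction: float
    n_hairpin_loops: int = 1


@dataclass
class CriteriaConfig:
    """Thresholds of the twelve hairpin criteria (printed defaults)."""

    max_stem_bulge: int = 12
    min_stem_pairs: int = 16
    min_length: int = 50
    max_loop: int = 200
    max_mature_bulge: int = 4
    max_mature_asym_bulge: int = 2
    max_mature_bulges: int = 2
    max_mature_errors: int = 4
    min_mature_pairs: int = 12
    min_mature_in_stem: float = 0.8
    max_mfe: float = -12.0
    mfei_default: float = 0.7
    mfei_with_target: float = 0.4
    mfei_high_confidence: float = 0.85


@dataclass
class CriteriaReport:
    checks: dict[str, bool]
    passed: bool
    mfei_high_confidence: bool = False

    def __getitem__(self, key: str) -> bool:
        return self.checks[key]


def locate_tag(tag: str, sequences: dict[str, str]) -> list[tuple[str, int, int, str]]:
    """All exact occurrences of a tag on both strands; coordinates are
    1-based inclusive on the forward strand."""
    hits = []
    rc = revcomp(tag)
    n = len(tag)
    for sid, seq in sequences.items():
        for probe, strand in ((tag, "+"), (rc, "-")):
            if strand == "-" and rc == tag:
                continue  # palindromic tag: forward hit already reported
            start = seq.find(probe)
            while start >= 0:
                hits.append((sid, start + 1, start + n, strand))
                start = seq.find(probe, start + 1)
    hits.sort(key=lambda h: (h[0], h[1], h[3]))
    return hits


@dataclass
class Window:
    sequence: str            # oriented so the tag reads 5'->3'
    locus: tuple[str, int, int, str]
    window_start: int        # 1-based genomic (forward strand)
    window_end: int
    tag_start: int           # 1-based within the oriented window
    tag_end: int
    arm: str


def extract_windows(
    locus: tuple[str, int, int, str],
    sequences: dict[str, str],
    flank: int = 200,
    max_len: int = 300,
) -> list[Window]:
    """Two candidate precursor windows per locus: tag on the 5' arm
    ([start - flank, tag_end + 20]) and on the 3' arm
    ([tag_start - 20, end + flank]), clipped to the sequence and to
    ``max_len`` (trimming the flank side).  Minus-strand windows are
    reverse-complemented so the tag reads 5'->3'."""
    if flank < 20:
        raise ValueError("flank must be >= 20")
    sid, start, end, strand = locus
    seq = sequences[sid]
    n = len(seq)
    tag_len = end - start + 1
    windows = []
    specs = [("5p", start - flank, end + 20), ("3p", start - 20, end + flank)]
    if strand == "-":
        # genomic arms swap when the tag is read from the minus strand
        specs = [("5p", start - 20, end + flank), ("3p", start - flank, end + 20)]
    for arm, ws, we in specs:
        ws, we = max(1, ws), min(n, we)
        if we - ws + 1 > max_len:
            if (arm == "5p") == (strand == "+"):
                ws = we - max_len + 1
            else:
                we = ws + max_len - 1
        sub = seq[ws - 1:we]
        if strand == "+":
            t0 = start - ws + 1
        else:
            sub = revcomp(sub)
            t0 = we - end + 1
        windows.append(Window(
            sequence=sub, locus=locus, window_start=ws, window_end=we,
            tag_start=t0, tag_end=t0 + tag_len - 1, arm=arm,
        ))
    return windows


def _hairpin_loops(pt: list[int]) -> list[tuple[int, int]]:
    """Innermost pairs (i, j): pairs enclosing no other pair."""
    loops = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def _stem_span(pt: list[int], loop: tuple[int, int]) -> tuple[int, int]:
    """Outermost pair of the simple stem closing the given hairpin loop:
    walk outward while the enclosing pair belongs to the same stem (only
    unpaired positions between consecutive pairs)."""
    a, b = loop
    while True:
        a2 = a - 1
        while a2 >= 0 and pt[a2] == -1:
            a2 -= 1
        if a2 < 0:
            break
        b2 = pt[a2]
        if b2 <= b:
            break  # different branch
        if any(pt[k] != -1 for k in range(b + 1, b2)):
            break  # multiloop boundary
        a, b = a2, b2
    return a, b


def _unpaired_runs(pt: list[int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal runs of unpaired positions within [lo, hi] (0-based incl.)."""
    runs = []
    i = lo
    while i <= hi:
        if pt[i] == -1:
            j = i
            while j + 1 <= hi and pt[j + 1] == -1:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def compute_metrics(hairpin: Hairpin) -> HairpinMetrics:
    """Thermodynamic and structural tallies of a candidate hairpin."""
    pt = parse_structure(hairpin.structure)
    n = len(pt)
    gc = gc_percent(hairpin.precursor_seq)
    amfe = abs(hairpin.mfe_kcal_mol) / n * 100.0
    mfei = amfe / gc if gc > 0 else None

    loops = _hairpin_loops(pt)
    ms, me = hairpin.mature_start - 1, hairpin.mature_end - 1  # 0-based

    if not loops:
        return HairpinMetrics(
            length=n, gc_percent=gc, mfe=hairpin.mfe_kcal_mol, amfe=amfe,
            mfei=mfei, stem_pairs=0, max_stem_bulge=0, loop_length=0,
            mature_pairs=0, mature_max_bulge=me - ms + 1, mature_max_asym_bulge=me - ms + 1,
            mature_bulge_count=1, mature_mismatch_nt=me - ms + 1,
            mature_in_stem_fraction=0.0, n_hairpin_loops=0,
        )

    # main stem: the hairpin loop whose stem contains (or is nearest to) the
    # mature region, preferring the one with the most pairs
    def stem_pair_count(loop):
        a, b = _stem_span(pt, loop)
        return sum(1 for i in range(a, b + 1) if pt[i] > i)

    main = max(loops, key=stem_pair_count)
    a, b = _stem_span(pt, main)
    li, lj = main
    loop_length = lj - li - 1
    stem_pairs = sum(1 for i in range(a, b + 1) if pt[i] > i)

    # largest one-sided gap between consecutive stem pairs
    max_stem_bulge = 0
    ca, cb = a, b
    while True:
        a2 = ca + 1
        while a2 < li and pt[a2] == -1:
            a2 += 1
        if a2 >= li or pt[a2] < a2:
            break
        b2 = pt[a2]
        max_stem_bulge = max(max_stem_bulge, a2 - ca - 1, cb - b2 - 1)
        ca, cb = a2, b2

    mature_len = me - ms + 1
    mature_pairs = sum(1 for i in range(ms, me + 1) if pt[i] != -1)
    mature_mismatch_nt = mature_len - mature_pairs

    runs = _unpaired_runs(pt, ms, me)
    mature_bulge_count = len(runs)
    mature_max_bulge = max((r[1] - r[0] + 1 for r in runs), default=0)

    # biased (one-sided) bulge: run size minus the opposite-strand gap
    mature_max_asym = 0
    for r0, r1 in runs:
        size = r1 - r0 + 1
        left = r0 - 1
        while left >= 0 and pt[left] == -1:
            left -= 1
        right = r1 + 1
        while right < n and pt[right] == -1:
            right += 1
        if left >= 0 and right < n and pt[left] != -1 and pt[right] != -1:
            opp = abs(pt[left] - pt[right]) - 1
            asym = max(0, size - max(opp, 0))
        else:
            asym = size  # overhang beyond the stem
        mature_max_asym = max(mature_max_asym, asym)

    stem_positions = set(range(a, li + 1)) | set(range(lj, b + 1))
    in_stem = sum(1 for i in range(ms, me + 1) if i in stem_positions)
    mature_in_stem_fraction = in_stem / mature_len if mature_len else 0.0

    return HairpinMetrics(
        length=n, gc_percent=gc, mfe=hairpin.mfe_kcal_mol, amfe=amfe, mfei=mfei,
        stem_pairs=stem_pairs, max_stem_bulge=max_stem_bulge,
        loop_length=loop_length, mature_pairs=mature_pairs,
        mature_max_bulge=mature_max_bulge, mature_max_asym_bulge=mature_max_asym,
        mature_bulge_count=mature_bulge_count, mature_mismatch_nt=mature_mismatch_nt,
        mature_in_stem_fraction=mature_in_stem_fraction,
        n_hairpin_loops=len(loops),
    )


def apply_criteria(
    metrics: HairpinMetrics,
    config: CriteriaConfig | None = None,
    has_target: bool = False,
) -> CriteriaReport:
    """Evaluate the twelve criteria independently; overall pass is their
    conjunction.  The MFEI threshold relaxes to ``mfei_with_target`` when a
    predicted target exists."""
    cfg = config or CriteriaConfig()
    mfei_cut = cfg.mfei_with_target if has_target else cfg.mfei_default
    checks = {
        "c1": metrics.max_stem_bulge <= cfg.max_stem_bulge,
        "c2": metrics.stem_pairs >= cfg.min_stem_pairs,
        "c3": metrics.length >= cfg.min_length,
        "c4": metrics.loop_length <= cfg.max_loop,
        "c5": metrics.mature_max_bulge <= cfg.max_mature_bulge,
        "c6": metrics.mature_max_asym_bulge <= cfg.max_mature_asym_bulge,
        "c7": metrics.mature_bulge_count <= cfg.max_mature_bulges,
        "c8": metrics.mature_mismatch_nt <= cfg.max_mature_errors,
        "c9": metrics.mature_pairs >= cfg.min_mature_pairs,
        "c10": metrics.mature_in_stem_fraction >= cfg.min_mature_in_stem,
        "c11": metrics.mfe <= cfg.max_mfe,
        "c12": metrics.mfei is not None and metrics.mfei >= mfei_cut,
    }
    return CriteriaReport(
        checks=checks,
        passed=all(checks.values()),
        mfei_high_confidence=metrics.mfei is not None
        and metrics.mfei >= cfg.mfei_high_confidence,
    )


@dataclass
class EvaluatedHairpin:
    hairpin: Hairpin
    metrics: HairpinMetrics
    report: CriteriaReport


def evaluate_window(
    window: Window,
    backend: FoldBackend | None = None,
    config: CriteriaConfig | None = None,
    has_target: bool = False,
) -> list[EvaluatedHairpin]:
    """Fold a window, excise each stem-loop component containing the tag,
    re-fold it as the candidate precursor, and score it against the
    criteria.  Multi-loop refolds fail the single-stem gate (rejected before
    the criteria)."""
    structure, _ = fold(window.sequence, backend)
    pt = parse_structure(structure)
    t0, t1 = window.tag_start - 1, window.tag_end - 1
    out = []
    for loop in _hairpin_loops(pt):
        a, b = _stem_span(pt, loop)
        if not (a <= t1 and t0 <= b):
            continue  # tag outside this stem-loop
        s = min(a, t0)
        e = max(b, t1)
        sub = window.sequence[s:e + 1]
        if len(sub) < 10:
            continue
        sub_structure, sub_mfe = fold(sub, backend)
        sub_pt = parse_structure(sub_structure)
        if len(_hairpin_loops(sub_pt)) != 1:
            continue  # single-stem gate
        hp = Hairpin(
            locus=window.locus,
            precursor_seq=sub,
            structure=sub_structure,
            mfe_kcal_mol=sub_mfe,
            mature_start=t0 - s + 1,
            mature_end=t1 - s + 1,
            arm="5p" if (t0 - s) < (len(sub) - 1 - (t1 - s)) else "3p",
        )
        metrics = compute_metrics(hp)
        out.append(EvaluatedHairpin(hp, metrics, apply_criteria(metrics, config, has_target)))
    return out


def best_hairpin(
    tag_seq: str,
    sequences: dict[str, str],
    loci: list[tuple[str, int, int, str]] | None = None,
    flank: int = 200,
    max_len: int = 300,
    backend: FoldBackend | None = None,
    config: CriteriaConfig | None = None,
    has_target: bool = False,
) -> tuple[EvaluatedHairpin | None, EvaluatedHairpin | None]:
    """(best passing hairpin, best overall hairpin) for a tag across all of
    its genomic loci and candidate windows.  "Best" is lowest MFE, ties
    broken by shorter precursor."""
    if loci is None:
        loci = locate_tag(tag_seq, sequences)
    candidates: list[EvaluatedHairpin] = []
    for locus in loci:
        for window in extract_windows(locus, sequences, flank, max_len):
            candidates.extend(evaluate_window(window, backend, config, has_target))
    if not candidates:
        return None, None
    key = lambda ev: (ev.hairpin.mfe_kcal_mol, len(ev.hairpin.precursor_seq))
    best_any = min(candidates, key=key)
    passing = [c for c in candidates if c.report.passed]
    best_pass = min(passing, key=key) if passing else None
    return best_pass, best_any


@dataclass
class MiRNACall:
    mature_seq: str
    count: int
    group: str                       # "1", "2a", "2b" or "3"
    family: str | None = None
    novel_id: str | None = None
    best_known: str | None = None
    mismatches: int | None = None
    hairpin: Hairpin | None = None
    metrics: HairpinMetrics | None = None
    report: CriteriaReport | None = None

    def __post_init__(self):
        if self.group == "3" and self.family is not None:
            raise ValueError("group 3 (novel) calls carry no family")
        if self.group == "1" and self.hairpin is None:
            raise ValueError("group 1 calls require a hairpin")


def classify(
    tag,
    homology,
    best_passing: EvaluatedHairpin | None,
    best_any: EvaluatedHairpin | None,
    has_locus: bool,
    novel_id: str | None = None,
) -> MiRNACall | None:
    """Screening-scheme grouping.

    group 1  = known-mature hit and a criteria-passing hairpin at a genomic
               locus containing the tag in an arm;
    group 2a = known-mature hit and a genomic locus whose window folds but
               fails >= 1 criterion;
    group 2b = known-mature hit with no genomic locus (supported only by the
               foreign precursor);
    group 3  = no known hit and a criteria-passing hairpin (novel).
    Tags with neither a hit nor a passing hairpin are discarded (None).
    """
    conserved = homology is not None
    if conserved:
        family, best_hit = homology
        if best_passing is not None:
            return MiRNACall(
                mature_seq=tag.sequence, count=tag.count, group="1",
                family=family, best_known=best_hit.known.name,
                mismatches=best_hit.mismatches, hairpin=best_passing.hairpin,
                metrics=best_passing.metrics, report=best_passing.report,
            )
        if has_locus:
            return MiRNACall(
                mature_seq=tag.sequence, count=tag.count, group="2a",
                family=family, best_known=best_hit.known.name,
                mismatches=best_hit.mismatches,
                hairpin=best_any.hairpin if best_any else None,
                metrics=best_any.metrics if best_any else None,
                report=best_any.report if best_any else None,
            )
        return MiRNACall(
            mature_seq=tag.sequence, count=tag.count, group="2b",
            family=family, best_known=best_hit.known.name,
            mismatches=best_hit.mismatches,
        )
    if best_passing is not None:
        return MiRNACall(
            mature_seq=tag.sequence, count=tag.count, group="3",
            novel_id=novel_id, hairpin=best_passing.hairpin,
            metrics=best_passing.metrics, report=best_passing.report,
        )
    return None
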