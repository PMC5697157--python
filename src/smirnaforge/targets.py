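"""Plant miRNA target prediction by complementarity scoring, and mapping of
5'RACE-derived transcript 5' ends to cleavage positions on the duplex.

Scoring follows the classic plant target-prediction penalty scheme: each
non-G:U mismatch costs 1.0, each G:U wobble 0.5 and each bulged nucleotide
1.0, with every penalty doubled at miRNA positions 2-13 (counted from the
miRNA 5' end); at most one single-nucleotide bulge is allowed per duplex and
sites scoring <= 4.0 are reported by default.  Plant miRNA-guided cleavage
canonically falls opposite the boundary between miRNA positions 10 and 11.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seq import to_rna

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

SEED_START, SEED_END = 2, 13  # doubled-penalty region, 1-based on the miRNA


@dataclass
class ScoreScheme:
    mismatch: float = 1.0
    gu: float = 0.5
    bulge: float = 1.0          # per bulged nucleotide
    seed_multiplier: float = 2.0
    seed_start: int = SEED_START
    seed_end: int = SEED_END

    def weight(self, position: int) -> float:
        return self.seed_multiplier if self.seed_start <= position <= self.seed_end else 1.0


@dataclass
class TargetAlignment:
    """A scored miRNA:mRNA duplex.

    ``states`` lists (miRNA position, state) in alignment order from the
    miRNA 5' end; a ``target_bulge`` entry carries the adjacent miRNA
    position and represents an extra unpaired target nucleotide.
    """

    mirna_seq: str
    transcript_id: str
    site_start: int  # 1-based inclusive on the transcript
    site_end: int
    site_seq: str
    states: list[tuple[int, str]]
    score: float
    bulge_kind: str = "none"     # none | target | mirna
    bulge_index: int | None = None  # target: site offset from 3' end; mirna: position


def _pair_state(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "match"
    if (m, t) in _GU:
        return "GU"
    return "mismatch"


def _score_arrangement(
    m: str, s: str, kind: str, bi: int | None, scheme: ScoreScheme
) -> tuple[float, list[tuple[int, str]]]:
    """Score one alignment arrangement.  ``s`` is the site 5'->3'; miRNA
    position i pairs the site's i-th nucleotide from its 3' end, adjusted
    for the bulge."""
    n, L = len(m), len(s)
    score = 0.0
    states: list[tuple[int, str]] = []
    if kind == "none":
        for i in range(1, n + 1):
            st = _pair_state(m[i - 1], s[L - i])
            if st == "GU":
                score += scheme.gu * scheme.weight(i)
            elif st == "mismatch":
                score += scheme.mismatch * scheme.weight(i)
            states.append((i, st))
    elif kind == "target":
        # site nucleotide bi (offset from the 3' end) is unpaired
        pos_b = min(max(bi + 1, 1), n)
        for t in range(L):
            if t == bi:
                score += scheme.bulge * scheme.weight(pos_b)
                states.append((pos_b, "target_bulge"))
                continue
            i = t + 1 if t < bi else t
            st = _pair_state(m[i - 1], s[L - 1 - t])
            if st == "GU":
                score += scheme.gu * scheme.weight(i)
            elif st == "mismatch":
                score += scheme.mismatch * scheme.weight(i)
            states.append((i, st))
    else:  # miRNA bulge: miRNA position bi unpaired
        for i in range(1, n + 1):
            if i == bi:
                score += scheme.bulge * scheme.weight(i)
                states.append((i, "mirna_bulge"))
                continue
            t = i - 1 if i < bi else i - 2
            st = _pair_state(m[i - 1], s[L - 1 - t])
            if st == "GU":
                score += scheme.gu * scheme.weight(i)
            elif st == "mismatch":
                score += scheme.mismatch * scheme.weight(i)
            states.append((i, st))
    return score, states


def score_duplex(
    mirna: str,
    target_site: str,
    scheme: ScoreScheme | None = None,
    transcript_id: str = "",
    site_start: int = 1,
) -> TargetAlignment:
    """Minimum-penalty duplex of a miRNA against a candidate site.

    The site is the mRNA subsequence 5'->3'; pairing is antiparallel
    (miRNA position 1 opposite the site's 3' end).  Site length must be
    within one nucleotide of the miRNA length (at most one bulge)."""
    scheme = scheme or ScoreScheme()
    m = to_rna(mirna)
    s = to_rna(target_site)
    n, L = len(m), len(s)
    if not n:
        raise ValueError("empty miRNA")
    if abs(L - n) > 1:
        raise ValueError("site length must be within miRNA length +/- 1")
    if L == n:
        arrangements = [("none", None)]
    elif L == n + 1:
        arrangements = [("target", bi) for bi in range(L)]
    else:
        arrangements = [("mirna", p) for p in range(1, n + 1)]
    best = None
    for kind, bi in arrangements:
        score, states = _score_arrangement(m, s, kind, bi, scheme)
        key = (score, bi if bi is not None else -1)
        if best is None or key < best[0]:
            best = (key, kind, bi, score, states)
    _, kind, bi, score, states = best
    return TargetAlignment(
        mirna_seq=m, transcript_id=transcript_id, site_start=site_start,
        site_end=site_start + L - 1, site_seq=s, states=states, score=score,
        bulge_kind=kind, bulge_index=bi,
    )


def score_from_states(alignment: TargetAlignment, scheme: ScoreScheme | None = None) -> float:
    """Recompute the penalty sum from the recorded states (invariant check)."""
    scheme = scheme or ScoreScheme()
    total = 0.0
    for pos, st in alignment.states:
        if st == "match":
            continue
        pen = {"GU": scheme.gu, "mismatch": scheme.mismatch,
               "target_bulge": scheme.bulge, "mirna_bulge": scheme.bulge}[st]
        total += pen * scheme.weight(pos)
    return total


def scan_transcriptome(
    mirna: str,
    transcripts: dict[str, str],
    cutoff: float = 4.0,
    scheme: ScoreScheme | None = None,
) -> list[TargetAlignment]:
    """All target sites scoring <= cutoff across the transcripts; window
    lengths |miRNA| - 1 .. |miRNA| + 1 are scanned and overlapping candidate
    windows are deduplicated to the local-minimum site.  Sorted by
    (score, transcript_id, start)."""
    scheme = scheme or ScoreScheme()
    n = len(mirna)
    results: list[TargetAlignment] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        candidates = []
        for L in (n - 1, n, n + 1):
            if L < 1:
                continue
            for start in range(0, len(seq) - L + 1):
                aln = score_duplex(mirna, seq[start:start + L], scheme,
                                   transcript_id=tid, site_start=start + 1)
                if aln.score <= cutoff:
                    candidates.append(aln)
        # cluster overlapping candidates, keep the best per cluster
        candidates.sort(key=lambda a: (a.site_start, a.site_end))
        cluster: list[TargetAlignment] = []
        cluster_end = -1
        for aln in candidates:
            if cluster and aln.site_start > cluster_end:
                results.append(min(cluster, key=lambda a: (a.score, a.site_start,
                                                           a.site_end - a.site_start)))
                cluster = []
                cluster_end = -1
            cluster.append(aln)
            cluster_end = max(cluster_end, aln.site_end)
        if cluster:
            results.append(min(cluster, key=lambda a: (a.score, a.site_start,
                                                       a.site_end - a.site_start)))
    results.sort(key=lambda a: (a.score, a.transcript_id, a.site_start))
    return results


@dataclass
class CleavageResult:
    alignment: TargetAlignment
    clone_positions: dict[tuple[int, int], int] = field(default_factory=dict)
    modal_boundary: tuple[int, int] | None = None
    modal_fraction: float = 0.0
    out_of_site: int = 0
    canonical: bool = False  # modal boundary at miRNA positions (10, 11)


def _partner_map(alignment: TargetAlignment) -> dict[int, int]:
    """transcript position -> paired miRNA position for the duplex."""
    n = len(alignment.mirna_seq)
    L = alignment.site_end - alignment.site_start + 1
    partners: dict[int, int] = {}
    for t in range(L):  # t = offset from the site 3' end
        tpos = alignment.site_end - t
        if alignment.bulge_kind == "target":
            if t == alignment.bulge_index:
                continue
            i = t + 1 if t < alignment.bulge_index else t
        elif alignment.bulge_kind == "mirna":
            i = t + 1 if t + 1 < alignment.bulge_index else t + 2
        else:
            i = t + 1
        if 1 <= i <= n:
            partners[tpos] = i
    return partners


def map_cleavage(
    alignment: TargetAlignment,
    five_prime_ends: list[tuple[int, int]],
) -> CleavageResult:
    """Translate observed transcript 5' ends (position, clone count) into
    cleavage boundaries in miRNA coordinates.

    A 5' end at transcript position p marks a cleaved phosphate between
    p - 1 and p; it is binned to the boundary between the miRNA positions
    pairing those two transcript nucleotides (i, i + 1 counted from the
    miRNA 5' end).  Plant slicing is canonical at (10, 11)."""
    partners = _partner_map(alignment)
    counts: dict[tuple[int, int], int] = {}
    out = 0
    for pos, c in five_prime_ends:
        i = partners.get(pos)
        if i is None or not (alignment.site_start <= pos <= alignment.site_end):
            out += c
            continue
        counts[(i, i + 1)] = counts.get((i, i + 1), 0) + c
    total = sum(counts.values())
    if not counts:
        warnings.warn("no 5' ends fall inside the target site")
        return CleavageResult(alignment=alignment, out_of_site=out)
    modal = max(counts.items(), key=lambda kv: (kv[1], -kv[0][0]))[0]
    return CleavageResult(
        alignment=alignment,
        clone_positions=counts,
        modal_boundary=modal,
        modal_fraction=counts[modal] / total,
        out_of_site=out,
        canonical=modal == (10, 11),
    )
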