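"""Conserved miRNA identification by homology to a known-miRNA reference.

A unique tag is called conserved when it matches a known mature miRNA with
at most 3 substitutions under an ungapped alignment allowing small terminal
shifts (isomiR-style 5'/3' end variation).  Families are parsed from
miRBase-style names (``ath-miR166a`` -> ``miR166``) and each tag is assigned
once, to its best hit, so family membership counts are disjoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .preprocess import UniqueTag
from .seq import to_dna

_FAMILY_RE = re.compile(r"(miR[0-9]+|let-?7)", re.IGNORECASE)


@dataclass(frozen=True)
class KnownMiRNA:
    name: str
    mature_seq: str  # stored as DNA; U/T-normalised on construction
    family: str
    precursor_seq: str | None = None

    @classmethod
    def from_header(cls, name: str, seq: str, precursor: str | None = None) -> "KnownMiRNA":
        return cls(name=name, mature_seq=to_dna(seq),
                   family=parse_family(name), precursor_seq=precursor)


def parse_family(name: str) -> str:
    """Family token of a miRBase-style name: species prefix and the trailing
    letter/number variant are stripped (``ath-miR166a-5p`` -> ``miR166``)."""
    m = _FAMILY_RE.search(name)
    if not m:
        return name
    tok = m.group(1)
    return "let-7" if tok.lower().startswith("let") else "miR" + re.sub(r"\D", "", tok)


@dataclass(frozen=True)
class HomologyHit:
    tag: UniqueTag
    known: KnownMiRNA
    mismatches: int
    offset: int  # tag start minus mature start


def _best_ungapped(tag: str, ref: str, max_mismatch: int, max_shift: int) -> tuple[int, int] | None:
    """Best (mismatches, offset) over allowed shifts, requiring overlap of at
    least len(tag) - 2; None when nothing qualifies."""
    best: tuple[int, int] | None = None
    for offset in range(-max_shift, max_shift + 1):
        lo = max(0, -offset)
        hi = min(len(tag), len(ref) - offset)
        overlap = hi - lo
        if overlap < len(tag) - 2 or overlap <= 0:
            continue
        mm = sum(tag[i] != ref[i + offset] for i in range(lo, hi))
        if mm > max_mismatch:
            continue
        key = (mm, abs(offset))
        if best is None or key < (best[0], abs(best[1])):
            best = (mm, offset)
    return best


def match_known(
    tag: UniqueTag,
    reference: list[KnownMiRNA],
    max_mismatch: int = 3,
    max_shift: int = 2,
) -> list[HomologyHit]:
    """All qualifying hits of a tag against the reference, sorted by
    (mismatches, |offset|, name)."""
    tseq = to_dna(tag.sequence)
    hits = []
    for known in reference:
        res = _best_ungapped(tseq, known.mature_seq, max_mismatch, max_shift)
        if res is not None:
            hits.append(HomologyHit(tag, known, res[0], res[1]))
    hits.sort(key=lambda h: (h.mismatches, abs(h.offset), h.known.name))
    return hits


def assign_family(hits: list[HomologyHit]) -> tuple[str, HomologyHit] | None:
    """Family of the best hit (fewest mismatches, smallest shift, then
    lexicographically smallest name); None sends the tag to the novel
    pipeline."""
    if not hits:
        return None
    best = hits[0]
    return best.known.family, best


def family_census(calls: list[HomologyHit]) -> pd.DataFrame:
    """Per-family member count (distinct mature tag sequences), total reads
    and read fraction over all conserved calls."""
    if not calls:
        return pd.DataFrame(columns=["family", "members", "reads", "read_fraction"])
    rows: dict[str, dict] = {}
    for hit in calls:
        fam = hit.known.family
        entry = rows.setdefault(fam, {"members": set(), "reads": 0})
        entry["members"].add(hit.tag.sequence)
        entry["reads"] += hit.tag.count
    total_reads = sum(e["reads"] for e in rows.values())
    df = pd.DataFrame([
        {"family": fam, "members": len(e["members"]), "reads": e["reads"],
         "read_fraction": e["reads"] / total_reads if total_reads else 0.0}
        for fam, e in rows.items()
    ])
    return df.sort_values(["reads", "family"], ascending=[False, True]).reset_index(drop=True)
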