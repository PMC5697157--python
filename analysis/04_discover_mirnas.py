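#!/usr/bin/env python
"""Conserved and novel miRNA discovery on the simulated bundle.

Matches the preprocessed tags against the known-miRNA reference (0-3
mismatches, +/-2 nt end shifts), evaluates hairpin windows at every genomic
locus under the twelve structural criteria, groups the calls (1 = known +
passing hairpin, 2a = known + imperfect hairpin, 2b = known without a
genomic locus, 3 = novel passing hairpin) and scores recovery against the
planted truth.  Outputs under results/discovery/.
"""

from pathlib import Path

import pandas as pd

from smirnaforge import homology as hom, pipeline as pl, preprocess as pre, synthetic as syn
from smirnaforge.seq import read_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "discovery"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    tags = [
        pre.UniqueTag(seq, int(name.rsplit("_x", 1)[1]))
        for name, seq in read_fasta(ROOT / "preprocess" / "tags.fa").items()
    ]
    scaffolds = read_fasta(ROOT / "sim" / "scaffolds.fa")
    known = [hom.KnownMiRNA.from_header(n, s)
             for n, s in read_fasta(ROOT / "sim" / "known_mirnas.fa").items()]

    calls = pl.discover(tags, scaffolds, known)
    report = {"schema_version": pl.SCHEMA_VERSION,
              "config": {}, "stages": {}, "calls": calls}
    hits = [hom.match_known(pre.UniqueTag(c.mature_seq, c.count), known)[0]
            for c in calls if c.group in ("1", "2a", "2b")]
    report["family_census"] = hom.family_census(hits)
    pl.write_report(report, OUT)

    truth_df = pd.read_csv(ROOT / "sim" / "truth.tsv", sep="\t")
    truth = [syn.TruthRecord(r.locus_id, r.scaffold_id, r.start, r.end,
                             r.mature_seq, r.arm, r.start, r.end,
                             bool(r.is_conserved))
             for r in truth_df.itertuples()]
    cmp = pl.compare_to_truth(calls, truth)

    groups = {g: sum(c.group == g for c in calls) for g in ("1", "2a", "2b", "3")}
    print(f"calls by group     {groups}")
    print(f"families           {len(report['family_census'])}")
    print(f"locus recovery     {cmp['n_recovered']}/{cmp['n_loci']} "
          f"({100 * cmp['recovery_fraction']:.0f}%)")
    print(f"background calls   {cmp['false_background_calls']}")
    mfeis = [c.metrics.mfei for c in calls if c.report and c.report.passed]
    print(f"MFEI of passing calls: {min(mfeis):.2f}-{max(mfeis):.2f}")
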