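#!/usr/bin/env python
"""Generate the default synthetic study bundle.

Writes genome-survey scaffolds with 20 planted miRNA hairpins (10 of them
with a diverged "foreign species" entry in the known-miRNA reference), a
small RNA library of 50 reads per locus with 10% ncRNA contaminants, and
microarray/Ct expression tables with a planted 8-fold change and one
anti-correlated miRNA-target pair.  Everything downstream (02-06) reads
from results/sim/.
"""

from pathlib import Path

from smirnaforge import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1

if __name__ == "__main__":
    paths = syn.simulate_bundle(
        OUT, seed=SEED, n_scaffolds=5, scaffold_length=200_000, n_hairpins=20,
        depth_per_locus=50, contaminant_fraction=0.1, error_rate=0.0,
        n_conserved=10,
    )
    print(f"synthetic bundle written to {OUT}:")
    for name, p in paths.items():
        print(f"  {name:12s} {p.name}")
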