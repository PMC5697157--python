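# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Read preprocessing

Reads are cleaned in a fixed order: 3' adapter trimming, then the length,
ambiguous-base and quality rules. The adapter is trimmed at the leftmost
exact match of its first 8 bases; adapters shorter than 8 nt are rejected
as a configuration error because shorter probes trim spuriously. "Low
quality" is operationalised as mean Phred < 20 when per-base qualities
exist; FASTA input skips the rule. A dust-style low-complexity filter
(Shannon entropy < 1 bit/nt) is available but off by default, since junk
removal of that kind is vendor-specific and has no published definition.
Contaminant (rRNA/tRNA/snoRNA/snRNA) matching is exact substring matching
on both strands by default — strandedness of public contaminant references
is unreliable — with an optional substitution allowance implemented as a
sliding Hamming scan (edit-distance tools were avoided because indels are
not part of the filter rule). The length distribution is computed before
size selection so the full profile is reported; size selection keeps
17–25 nt inclusive.

Invariants maintained: every read is accounted for exactly once across
kept/removed partitions at each stage; cleaning and size selection are
idempotent.

## k-mer genome survey

k-mers (default k = 17) are counted on the given strand; windows containing
N restart after the N. Canonical (strand-merged) counting is available
behind a flag but off by default: the survey formula is stated
strand-naively, and the synthetic survey uses single-strand fragments.
The coverage peak is the argmax of the multiplicity histogram over depths
≥ 4 (min_depth excludes the sequencing-error peak at depth 1–3), ties
broken toward the smaller depth. Genome size is total k-mer count divided
by peak depth, reported both exactly and truncated (not rounded) to two
decimals in Gb — truncation because the published worked example
(67,780,201,950 / 21 = 3.2276 Gb → 3.22 Gb) truncates. Coverage is the
plain ratio of sequenced bases to genome size; no heterozygosity or repeat
modelling of the spectrum is attempted. Synthetic survey fragments are
1 kb: each fragment loses k−1 terminal k-mers, so short fragments would
bias the size estimate down by roughly (k−1)/L; at L = 1000 the bias is
1.6%, within the 5% recovery tolerance the tests assert.

## Conserved miRNA homology

A tag is conserved when an ungapped alignment to a known mature miRNA has
≤ 3 substitutions over an overlap of at least (tag length − 2), allowing
±2 nt terminal shifts. Whole-tag matching with shifts, rather than a
seed-region-only rule, is used because only the 0–3 mismatch bound is
published for this class of pipeline; shifts absorb isomiR end variation.
Both sides are normalised to the DNA alphabet, making U/T equivalent.
A tag hitting several references is assigned once, to the best hit
(fewest mismatches, smallest |shift|, then lexicographically smallest
name), so family membership counts are disjoint. Families are parsed from
miRBase-style names (`ath-miR166a-5p` → `miR166`; `let-7` handled
specially).

## Hairpin evaluation

Each genomic tag locus seeds two windows, placing the tag on the 5' arm
([start − flank, tag end + 20]) or the 3' arm ([tag start − 20,
end + flank]); flank defaults to 200 nt and windows are clipped to 300 nt
from the flank side. Minus-strand windows are reverse-complemented so the
tag reads 5'→3'.

Windows are folded at minimum free energy (ViennaRNA 2.x behind a
pluggable backend interface; any engine returning a dot-bracket MFE
structure can be substituted, and stored hairpins re-validate by
re-folding). A folded window of 250+ nt almost always carries incidental
stems in its random or genomic flanks, so the criteria are not applied to
the window directly: the stem-loop component containing the tag is excised
— walk outward from the hairpin loop while consecutive pairs enclose only
unpaired bases, extend the span to cover the mature tag — and re-folded as
the candidate precursor. Re-folds with more than one hairpin loop fail a
single-stem gate before any criterion is applied (the model assumes
canonical stem-loops; multi-branch structures are out of scope). Among
passing candidates across all loci and windows, the lowest-MFE one wins,
ties broken by shorter precursor.

Metrics: AMFE = (|MFE| / length) × 100; MFEI = AMFE / GC% with GC%
expressed as a percentage value, so MFEI is a positive index typically in
(0, 2.8] for genuine precursors; GC% = 0 makes MFEI undefined and fails
the MFEI criterion. Stem pairs are counted along the main stem; a stem
bulge is the larger one-sided gap between consecutive stem pairs.
Mature-region tallies run over the tag interval on the precursor: paired
nucleotides ("base pairs in the mature region"), unpaired nucleotides
("errors"), maximal unpaired runs (bulges; their count and largest size),
and the biased (one-sided) bulge size, defined as a run's length minus the
opposite-strand gap of the enclosing pairs. The in-stem fraction is the
share of mature nucleotides lying between the outermost and innermost pair
of the main stem (loop and overhang positions excluded).

The twelve criteria and their default thresholds:

| # | check | threshold |
|---|-------|-----------|
| 1 | largest stem bulge | ≤ 12 nt |
| 2 | stem base pairs | ≥ 16 |
| 3 | hairpin length | ≥ 50 nt |
| 4 | terminal loop | ≤ 200 nt |
| 5 | largest mature-region bulge | ≤ 4 nt |
| 6 | largest one-sided mature bulge | ≤ 2 nt |
| 7 | mature-region bulges | ≤ 2 |
| 8 | unpaired mature nucleotides | ≤ 4 |
| 9 | mature-region base pairs | ≥ 12 |
| 10 | mature fraction in stem | ≥ 80% |
| 11 | MFE | ≤ −12 kcal/mol |
| 12 | MFEI | ≥ 0.7 (≥ 0.4 with a predicted target) |

Criterion 1 is conventionally printed with the inequality reversed in this
literature; a *minimum* 12-nt bulge would contradict every other hairpin
quality requirement, so it is implemented as a maximum, configurable like
every other threshold. Criterion 11's −12 kcal/mol is unusually permissive
but retained as the printed default. MFEI ≥ 0.85 is additionally flagged
as high confidence. All criteria are evaluated independently and the
overall verdict is their conjunction, which makes the gate monotone in
each threshold.

Grouping: group 1 = known-mature hit plus a criteria-passing hairpin at a
genomic locus containing the tag in an arm; 2a = known hit plus a genomic
locus whose windows fold but fail ≥ 1 criterion; 2b = known hit with no
genomic locus (supported only by the foreign precursor); 3 = no known hit
but a passing hairpin, numbered `csn-miRn{k}` in descending-count order.
Tags with neither are discarded. The 2a/2b division (imperfect hairpin vs
no locus) is a stated convention of this package. Coordinates are 1-based
inclusive throughout; minus-strand precursors are reported in
precursor-local coordinates plus the genomic locus.

## Target prediction and cleavage mapping

Duplex scoring uses the classic plant penalty scheme: non-G:U mismatch
1.0, G:U wobble 0.5, each bulged nucleotide 1.0, all penalties doubled at
miRNA positions 2–13 from the 5' end; the published description of this
class of scorer names the scheme without printing the table, so the values
follow the cited method's convention and are exposed as configuration.
At most one single-nucleotide bulge is allowed per duplex (larger loops are
rejected, keeping the scan O(L·n) per transcript); the reported alignment
is the minimum-score arrangement over all bulge placements, and a bulge's
doubling position is the miRNA position 3'-adjacent to it. "Maximum
expectation" filtering is realised as the score cutoff (default 4.0); no
probabilistic model is implemented. Overlapping candidate windows collapse
to the local-minimum site.

Cleavage mapping translates an observed transcript 5' end at position p to
the boundary between the miRNA positions pairing p and p−1 (the cleaved
phosphate lies between them); counts aggregate per boundary, and the modal
boundary, its clone fraction and a canonical flag (modal = 10/11, the
plant slicing position) are reported. Clones falling outside the site or
opposite a bulge are tallied separately, so clone counts conserve.

## Expression

Microarray CV is computed on background-subtracted replicate signals
(sample SD / mean) before normalization, since the CV rule belongs to the
pre-analysis spot filters; whether the 3× background-SD rule applies to
raw or subtracted signal is not standardised, and the subtracted signal is
used (configurable). Statuses are mutually exclusive in the order
removed_qc → non_expressed (< 30) → low_abundance (< 100) → expressed.
LOWESS normalization is MA-style against a mean pseudo-array — each
channel's log2 ratio to the per-probe mean log2 signal is smoothed over
intensity (span 0.3) and subtracted — the standard approach for
single-channel miRNA arrays, and exactly invariant on identical channels.

qRT-PCR conventions are pinned so that higher abundance gives a larger
value in both directions of use: relative abundance 2^ΔCt with
ΔCt = Ct_control − Ct_gene (U6 for miRNAs, GAPDH for mRNAs), and fold
change 2^−ΔΔCt with ΔCt = Ct_gene − Ct_control, reference sample ≡ 1
exactly. Correlation of miRNA and target profiles reports Pearson and
Spearman coefficients with a direction flag; zero-variance profiles raise
rather than returning NaN. Amplification-efficiency estimation from
standard curves is out of scope.

## Enrichment

Over-representation only: the one-sided hypergeometric upper tail
P(X ≥ k) for k target genes among n tested, K annotated among N
background. The background universe defaults to all genes declared in the
annotation; unannotated genes stay in the universe. Raw p ≤ 0.05 flags
enrichment; Benjamini–Hochberg q-values are an opt-in column, not used for
the flag, mirroring the raw-p practice of the workflows this reproduces.
GO tabulation reports per-namespace term percentages of term-assignments
(a gene with terms in two namespaces counts once per namespace). Ontology
graph propagation is out of scope; annotations are consumed pre-propagated.

## Synthetic data: what it does and does not emulate

The generator plants hairpins `arm + loop + perturbed-revcomp(arm)` in
i.i.d. uniform ACGT background. Defaults: 24-nt arms (the mature is the
full arm), 8-nt loops, 90% Watson–Crick stems with the remainder G:U or
mismatch — thermodynamically dominant stems, so recovery does not hinge on
a particular folding engine — 20 hairpins across 1 Mb of scaffolds, 50
reads per locus, 10% contaminants. Reads are sampled with joint 5'/3' end
jitter whose weights put the aggregate length mode at 24 nt and a
secondary mode at 21 nt, matching the shape of real plant small RNA
libraries; substitution errors are i.i.d. per base. The known-miRNA
reference emits "foreign species" matures diverged by 0–2 substitutions by
default (within the 3-mismatch homology budget). Expression tables plant
fold changes as −log2(f) Ct shifts against constant controls and include
one miRNA–target pair with exactly inverted fold changes, so the pair's
log2 relative-expression profiles correlate at r = −1 at zero noise.

Deliberately not emulated: RNA degradation, isomiR biology beyond end
jitter, adapter chemistry beyond a single configurable 3' adapter,
repetitive or heterozygous genome structure, multi-mapping loci, and
cross-hybridisation on the array. Passing tests therefore demonstrate
correctness of the algorithms under clean, single-copy conditions — not
robustness to the full noise structure of real libraries, where homologous
family members, repeat-derived siRNAs and degradation products make
precision/recall trade-offs material.

## Problem sizes

The default synthetic study uses 5 × 200 kb scaffolds, 20 hairpin loci at
depth 50 (~1,100 reads), a 100-kb genome at depth 20 for the survey
recovery check, 1,000 random duplex pairs for the scorer/oracle
comparison, and complete draw enumeration for hypergeometric universes up
to N = 12 — sizes chosen so each analysis expresses the property it
demonstrates while the whole suite runs in a couple of minutes on one CPU.

## Known limitations

Tags are located by exact match only; a tag mutated relative to its locus
(sequencing error) finds no hairpin and can only surface as group 2b.
`find_peak` assumes a unimodal coverage peak above the error depths —
strongly heterozygous spectra would need mixture modelling. The duplex
scanner is exhaustive rather than seeded, which is exact but slow beyond a
few hundred kb of transcriptome per miRNA. The stem-loop excision takes
the single best component per window; tandem hairpins closer than a window
length are evaluated independently per tag locus, not jointly.
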