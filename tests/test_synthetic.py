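"""Generator guarantees: determinism, truth-table invariants, read jitter
and noise models, reference divergence and planted expression signals."""

import numpy as np
import pytest

from smirnaforge import expression as expr
from smirnaforge import synthetic as syn
from smirnaforge.seq import hamming


def test_planted_precursor_geometry():
    scaffolds, truth = syn.make_genome(
        seed=1, n_scaffolds=1, scaffold_length=2000, n_hairpins=2,
        stem_len=22, loop_len=8,
    )
    assert len(scaffolds) == 1
    assert len(truth) == 2
    for rec in truth:
        assert rec.precursor_end - rec.precursor_start + 1 == 2 * 22 + 8 == 52
        # mature is an exact subsequence of the planted precursor and genome
        assert rec.mature_seq in rec.precursor_seq
        seq = scaffolds[rec.scaffold_id]
        assert seq[rec.precursor_start - 1:rec.precursor_end] == rec.precursor_seq
        assert seq[rec.mature_start - 1:rec.mature_end] == rec.mature_seq
    assert len({r.locus_id for r in truth}) == 2


def test_background_only_genome_has_empty_truth():
    scaffolds, truth = syn.make_genome(seed=2, n_scaffolds=2,
                                       scaffold_length=1000, n_hairpins=0)
    assert truth == []
    assert all(len(s) == 1000 for s in scaffolds.values())


def test_same_seed_is_byte_identical(tmp_path):
    a = syn.simulate_bundle(tmp_path / "a", seed=7, n_scaffolds=1,
                            scaffold_length=10_000, n_hairpins=3,
                            depth_per_locus=10)
    b = syn.simulate_bundle(tmp_path / "b", seed=7, n_scaffolds=1,
                            scaffold_length=10_000, n_hairpins=3,
                            depth_per_locus=10)
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes(), key


def test_infeasible_packing_raises():
    with pytest.raises(RuntimeError, match="infeasible packing"):
        syn.make_genome(seed=3, n_scaffolds=1, scaffold_length=300,
                        n_hairpins=10, stem_len=20, loop_len=8)


def test_noise_free_reads_equal_mature():
    scaffolds, truth = syn.make_genome(seed=4, n_scaffolds=1,
                                       scaffold_length=5000, n_hairpins=1)
    reads = syn.make_reads(truth, scaffolds, depth_per_locus=100,
                           error_rate=0.0, seed=5, jitter=False)
    assert len(reads) == 100
    assert all(seq == truth[0].mature_seq for _, seq in reads)


def test_all_contaminant_reads_match_reference():
    scaffolds, truth = syn.make_genome(seed=6, n_scaffolds=1,
                                       scaffold_length=5000, n_hairpins=1)
    contaminants = syn.make_contaminants(7)
    reads = syn.make_reads(truth, scaffolds, depth_per_locus=10,
                           contaminant_fraction=1.0, contaminants=contaminants,
                           seed=8)
    refs = [seq for _, seq in contaminants]
    assert reads
    assert all(any(seq in ref for ref in refs) for _, seq in reads)


def test_substitution_rate_matches_binomial_mean():
    """At error rate 0.01 a 24-nt read carries 0.24 substitutions on
    average; the observed mean over 1000 reads stays within [0.15, 0.35]."""
    scaffolds, truth = syn.make_genome(seed=9, n_scaffolds=1,
                                       scaffold_length=5000, n_hairpins=1)
    reads = syn.make_reads(truth, scaffolds, depth_per_locus=1000,
                           error_rate=0.01, seed=10, jitter=False)
    mature = truth[0].mature_seq
    mean_subs = np.mean([hamming(seq, mature) for _, seq in reads])
    assert 0.15 <= mean_subs <= 0.35


def test_jittered_reads_align_to_precursor_arms():
    """Truth-consistency: every non-contaminant read is an exact genomic
    substring within +/-2 nt of the planted mature arm."""
    scaffolds, truth = syn.make_genome(seed=11, n_scaffolds=1,
                                       scaffold_length=20_000, n_hairpins=4)
    reads = syn.make_reads(truth, scaffolds, depth_per_locus=25, seed=12)
    by_locus = {r.locus_id: r for r in truth}
    for rid, seq in reads:
        rec = by_locus[rid.split("_", 1)[1]]
        genome = scaffolds[rec.scaffold_id]
        pos = genome.find(seq)
        assert pos >= 0
        assert abs((pos + 1) - rec.mature_start) <= 2
        assert abs((pos + len(seq)) - rec.mature_end) <= 2


def test_read_length_mode_is_24_with_secondary_21():
    scaffolds, truth = syn.make_genome(seed=13, n_scaffolds=2,
                                       scaffold_length=50_000, n_hairpins=10)
    reads = syn.make_reads(truth, scaffolds, depth_per_locus=100, seed=14)
    lengths = np.array([len(s) for _, s in reads])
    counts = {L: int((lengths == L).sum()) for L in np.unique(lengths)}
    ranked = sorted(counts, key=counts.get, reverse=True)
    assert ranked[0] == 24
    assert ranked[1] == 21


class TestKnownReference:
    def test_zero_divergence_is_identical(self):
        _, truth = syn.make_genome(seed=15, n_scaffolds=1,
                                   scaffold_length=10_000, n_hairpins=3)
        known = syn.make_known_reference(truth, 3, max_divergence=0, seed=16)
        assert [s for _, s in known] == [r.mature_seq for r in truth]
        assert all(r.is_conserved for r in truth)

    def test_empty_reference(self):
        _, truth = syn.make_genome(seed=17, n_scaffolds=1,
                                   scaffold_length=10_000, n_hairpins=2)
        assert syn.make_known_reference(truth, 0) == []
        assert not any(r.is_conserved for r in truth)

    def test_divergence_bounded_by_max(self):
        _, truth = syn.make_genome(seed=18, n_scaffolds=1,
                                   scaffold_length=20_000, n_hairpins=6)
        known = syn.make_known_reference(truth, 6, max_divergence=3, seed=19)
        for rec, (_, seq) in zip(truth, known):
            assert hamming(rec.mature_seq, seq) <= 3

    def test_excess_divergence_warns(self):
        _, truth = syn.make_genome(seed=20, n_scaffolds=1,
                                   scaffold_length=10_000, n_hairpins=1)
        with pytest.warns(UserWarning, match="max_divergence"):
            syn.make_known_reference(truth, 1, max_divergence=4, seed=21)


class TestExpressionTables:
    def _tables(self, folds, noise=0.0, seed=30):
        scaffolds, truth = syn.make_genome(seed=22, n_scaffolds=1,
                                           scaffold_length=10_000, n_hairpins=2)
        fc = {truth[0].locus_id: folds}
        ma, ct = syn.make_expression_tables(truth, len(folds), fc,
                                            seed=seed, noise_cv=noise)
        return truth, ma, ct

    def test_unit_fold_change_recovered(self):
        truth, _, ct = self._tables([1.0, 1.0, 1.0])
        fc = expr.fold_change_ddct(ct, truth[0].locus_id, "tissue2", "tissue1")
        assert fc == pytest.approx(1.0)

    def test_planted_fold_8_shifts_ct_by_3_cycles(self):
        truth, _, ct = self._tables([1.0, 8.0])
        g = truth[0].locus_id
        ct1 = ct[(ct["sample"] == "tissue1") & (ct["gene"] == g)]["ct"].mean()
        ct2 = ct[(ct["sample"] == "tissue2") & (ct["gene"] == g)]["ct"].mean()
        assert ct2 - ct1 == pytest.approx(-3.0)

    def test_planted_pair_is_anticorrelated(self):
        truth, _, ct = self._tables([1.0, 4.0, 0.5, 2.0])
        g = truth[0].locus_id
        tissues = [f"tissue{i}" for i in range(1, 5)]
        mir = [np.log2(expr.fold_change_ddct(ct, g, t, "tissue1")) for t in tissues]
        tgt = [np.log2(expr.fold_change_ddct(ct, f"target_of_{g}", t, "tissue1",
                                             control="GAPDH")) for t in tissues]
        res = expr.correlate_pairs(mir, tgt)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.direction == "negative"

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            self._tables([1.0, 0.0])
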