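"""Hairpin evaluation: folding contracts, structure parsing, window
arithmetic, metric formulas, the twelve-criterion gate and grouping."""

import dataclasses

import pytest

from smirnaforge import hairpin as hp
from smirnaforge.preprocess import UniqueTag
from smirnaforge.seq import revcomp

ARM = "GCTAGGCTGATCGGACCTGCAG"  # 22 nt, designed stem arm
PERFECT = ARM + "GCTTAAGC" + revcomp(ARM)  # 22 + 8 + 22 = 52 nt


class TestFold:
    def test_unpairable_sequence_is_open(self):
        structure, mfe = hp.fold("A" * 10)
        assert structure == "." * 10
        assert mfe == 0.0

    def test_designed_stem_folds_fully(self):
        structure, mfe = hp.fold(PERFECT)
        pt = hp.parse_structure(structure)
        assert mfe < 0
        # every arm position pairs into the stem
        assert all(pt[i] != -1 for i in range(22))
        assert all(pt[i] != -1 for i in range(30, 52))

    def test_fold_is_deterministic(self):
        assert hp.fold(PERFECT) == hp.fold(PERFECT)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            hp.fold("ACGUXACGUACGU")


class TestParseStructure:
    def test_simple_hairpin(self):
        pt = hp.parse_structure("(((...)))")
        assert pt[0] == 8 and pt[1] == 7 and pt[2] == 6
        assert pt[3] == pt[4] == pt[5] == -1

    def test_open_structure(self):
        assert hp.parse_structure(".........") == [-1] * 9

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError, match="unbalanced"):
            hp.parse_structure("(()")
        with pytest.raises(ValueError, match="unbalanced"):
            hp.parse_structure("())")


class TestLocateTag:
    def test_planted_tag_found_at_truth_coordinates(self):
        seqs = {"s": "A" * 100 + ARM + "A" * 100}
        assert hp.locate_tag(ARM, seqs) == [("s", 101, 122, "+")]

    def test_absent_tag(self):
        assert hp.locate_tag("G" * 25, {"s": "A" * 200}) == []

    def test_both_strands_reported(self):
        seqs = {"s": "A" * 50 + ARM + "T" * 50 + revcomp(ARM) + "A" * 50}
        loci = hp.locate_tag(ARM, seqs)
        assert len(loci) == 2
        assert {l[3] for l in loci} == {"+", "-"}


class TestExtractWindows:
    SEQS = {"s": "A" * 2000}

    def test_window_arithmetic(self):
        w5, w3 = hp.extract_windows(("s", 1000, 1021, "+"), self.SEQS, flank=100)
        assert (w5.window_start, w5.window_end) == (900, 1041)
        assert (w3.window_start, w3.window_end) == (980, 1121)
        assert w5.sequence == self.SEQS["s"][899:1041]
        # tag coordinates within the window bracket the genomic tag
        assert w5.tag_start == 101 and w5.tag_end == 122

    def test_clipped_at_sequence_start(self):
        w5, _ = hp.extract_windows(("s", 5, 26, "+"), self.SEQS, flank=100)
        assert w5.window_start == 1

    def test_minus_strand_is_reverse_complemented(self):
        seq = {"s": "".join("ACGT"[(i * 7) % 4] for i in range(400))}
        locus = ("s", 150, 171, "-")
        for w in hp.extract_windows(locus, seq, flank=50):
            fwd = seq["s"][w.window_start - 1:w.window_end]
            assert w.sequence == revcomp(fwd)
            tag = w.sequence[w.tag_start - 1:w.tag_end]
            assert tag == revcomp(seq["s"][149:171])

    def test_max_len_respected(self):
        for w in hp.extract_windows(("s", 1000, 1021, "+"), self.SEQS,
                                    flank=290, max_len=300):
            assert len(w.sequence) <= 300


def _metrics(**overrides):
    """Baseline metrics of a clean passing hairpin, overridable per field."""
    base = dict(
        length=60, gc_percent=50.0, mfe=-30.0, amfe=50.0, mfei=1.0,
        stem_pairs=22, max_stem_bulge=2, loop_length=8, mature_pairs=20,
        mature_max_bulge=1, mature_max_asym_bulge=1, mature_bulge_count=1,
        mature_mismatch_nt=2, mature_in_stem_fraction=1.0, n_hairpin_loops=1,
    )
    base.update(overrides)
    return hp.HairpinMetrics(**base)


class TestComputeMetrics:
    def _hairpin(self, seq, structure, mfe, ms=1, me=None):
        return hp.Hairpin(("s", 1, len(seq), "+"), seq, structure, mfe,
                          ms, me or len(seq) // 2, "5p")

    def test_amfe_and_mfei_formulas(self):
        # length 100, MFE -50, GC 50% -> AMFE 50, MFEI 1.0
        seq = ("GC" * 25 + "AT" * 25)
        structure = "(" * 40 + "." * 20 + ")" * 40
        m = hp.compute_metrics(self._hairpin(seq, structure, -50.0, 1, 40))
        assert m.amfe == pytest.approx(50.0)
        assert m.mfei == pytest.approx(1.0)

    def test_zero_mfe_gives_zero_indices(self):
        seq = "GCAT" * 15
        m = hp.compute_metrics(self._hairpin(seq, "." * 60, 0.0, 1, 20))
        assert m.amfe == 0.0 and m.mfei == 0.0

    def test_mfei_hand_check(self):
        # length 80, MFE -40, GC 40% -> AMFE 50, MFEI 1.25
        seq = "GGCCATATAT" * 8  # 40% GC
        structure = "(" * 30 + "." * 20 + ")" * 30
        m = hp.compute_metrics(self._hairpin(seq, structure, -40.0, 1, 30))
        assert m.mfei == pytest.approx(1.25)

    def test_designed_hairpin_tallies(self):
        structure, mfe = hp.fold(PERFECT)
        m = hp.compute_metrics(self._hairpin(PERFECT, structure, mfe, 1, 22))
        assert m.length == 52
        assert m.stem_pairs >= 16
        assert m.mature_pairs >= 12
        assert m.loop_length >= 3
        assert m.mature_in_stem_fraction >= 0.8
        assert m.n_hairpin_loops == 1

    def test_zero_gc_flags_undefined_mfei(self):
        m = hp.compute_metrics(self._hairpin("AT" * 30, "." * 60, 0.0, 1, 20))
        assert m.mfei is None
        report = hp.apply_criteria(m)
        assert not report["c12"] and not report.passed


# (criterion, metric field, passing value at threshold, failing value)
BOUNDARIES = [
    ("c1", "max_stem_bulge", 12, 13),
    ("c2", "stem_pairs", 16, 15),
    ("c3", "length", 50, 49),
    ("c4", "loop_length", 200, 201),
    ("c5", "mature_max_bulge", 4, 5),
    ("c6", "mature_max_asym_bulge", 2, 3),
    ("c7", "mature_bulge_count", 2, 3),
    ("c8", "mature_mismatch_nt", 4, 5),
    ("c9", "mature_pairs", 12, 11),
    ("c10", "mature_in_stem_fraction", 0.8, 0.79),
    ("c11", "mfe", -12.0, -11.9),
    ("c12", "mfei", 0.7, 0.69),
]


class TestApplyCriteria:
    @pytest.mark.parametrize("crit,fld,ok,bad", BOUNDARIES)
    def test_each_criterion_flips_at_printed_threshold(self, crit, fld, ok, bad):
        at = hp.apply_criteria(_metrics(**{fld: ok}))
        assert at[crit] and at.passed
        beyond = hp.apply_criteria(_metrics(**{fld: bad}))
        assert not beyond[crit] and not beyond.passed
        assert all(v for c, v in beyond.checks.items() if c != crit)

    def test_mfei_relaxes_to_04_with_target(self):
        m = _metrics(mfei=0.5)
        assert not hp.apply_criteria(m).passed
        assert hp.apply_criteria(m, has_target=True).passed
        assert not hp.apply_criteria(_metrics(mfei=0.39), has_target=True).passed

    def test_high_confidence_mfei_flag(self):
        assert hp.apply_criteria(_metrics(mfei=0.9)).mfei_high_confidence
        assert not hp.apply_criteria(_metrics(mfei=0.8)).mfei_high_confidence

    def test_perfect_designed_hairpin_passes_all(self):
        structure, mfe = hp.fold(PERFECT)
        hairpin = hp.Hairpin(("s", 1, 52, "+"), PERFECT, structure, mfe, 1, 22, "5p")
        report = hp.apply_criteria(hp.compute_metrics(hairpin))
        assert report.passed, report.checks

    def test_truncated_hairpin_fails_length(self):
        report = hp.apply_criteria(_metrics(length=48))
        assert not report["c3"] and not report.passed

    def test_relaxing_thresholds_is_monotone(self):
        """Loosening any single threshold never turns a pass into a fail."""
        m = _metrics()
        base = hp.apply_criteria(m)
        assert base.passed
        cfg = hp.CriteriaConfig()
        for f in dataclasses.fields(cfg):
            v = getattr(cfg, f.name)
            looser = v + 5 if f.name.startswith("max") else v - 5
            relaxed = dataclasses.replace(cfg, **{f.name: looser})
            assert hp.apply_criteria(m, relaxed).passed


import numpy as _np

_BG = "".join(_np.random.default_rng(555).choice(list("ACGT"), 120))


class TestEvaluateAndClassify:
    SEQS = {"s": _BG + PERFECT + _BG[::-1]}

    def _best(self):
        return hp.best_hairpin(ARM, self.SEQS)

    def test_planted_hairpin_recovered_and_revalidates(self):
        best_pass, _ = self._best()
        assert best_pass is not None
        hpn = best_pass.hairpin
        structure, mfe = hp.fold(hpn.precursor_seq)
        assert structure == hpn.structure
        assert mfe == pytest.approx(hpn.mfe_kcal_mol)
        mature = hpn.precursor_seq[hpn.mature_start - 1:hpn.mature_end]
        assert mature == ARM

    def test_group1_for_known_hit_with_passing_hairpin(self):
        best_pass, best_any = self._best()
        tag = UniqueTag(ARM, 9)
        known = hp.classify(tag, ("miR166", _FakeHit()), best_pass, best_any, True)
        assert known.group == "1" and known.family == "miR166"

    def test_group2a_for_known_hit_with_failing_hairpin(self):
        _, best_any = self._best()
        tag = UniqueTag(ARM, 9)
        call = hp.classify(tag, ("miR166", _FakeHit()), None, best_any, True)
        assert call.group == "2a"

    def test_group2b_for_known_hit_without_locus(self):
        call = hp.classify(UniqueTag(ARM, 3), ("miR166", _FakeHit()), None, None, False)
        assert call.group == "2b" and call.hairpin is None

    def test_group3_novel_with_fresh_id(self):
        best_pass, best_any = self._best()
        call = hp.classify(UniqueTag(ARM, 2), None, best_pass, best_any, True,
                           novel_id="csn-miRn1")
        assert call.group == "3" and call.novel_id == "csn-miRn1"
        assert call.family is None

    def test_unsupported_tag_discarded(self):
        assert hp.classify(UniqueTag(ARM, 1), None, None, None, False) is None


class _FakeHit:
    class known:
        name = "ath-miR166a"
    mismatches = 1
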