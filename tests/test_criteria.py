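"""Arm assignment, star-mismatch counting, loop/break rule, AMFE/MFEI."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirssr.criteria import (
    CriteriaThresholds, assign_arm, check_loop_break, compute_mfei,
    count_star_mismatches, evaluate_candidate, summarize_mfei, terminal_loop,
)
from mirssr.fold import STACKING, fold_mfe
from mirssr.homology import MatureRef, Transcript, extract_precursor_window, \
    find_homology_hits
from mirssr.io import rna_to_dna
from mirssr.simulate import _arm_decoy, _loop_break_decoy, build_hairpin

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
MIR171 = "UUGAGCCGCGUCAAUAUCUCC"


def _span_of(pre_rna, mature):
    off = pre_rna.find(mature)
    assert off >= 0
    return (off, off + len(mature))


class TestAssignArm:
    def test_planted_5p_precursor(self):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1)
        fold = fold_mfe(pre, STACKING)
        assert assign_arm(fold, _span_of(pre, LET7)) == "5p"

    def test_planted_3p_precursor(self):
        pre = build_hairpin(LET7, "3p", 6, 0, seed=1, stem_ext=8)
        fold = fold_mfe(pre, STACKING)
        assert assign_arm(fold, _span_of(pre, LET7)) == "3p"

    def test_mature_straddling_terminal_loop_is_none(self):
        stem = "GCGGCAGCCGGC"
        pre = stem + "AACAA" + "GCCGGCUGCCGC"
        fold = fold_mfe(pre, STACKING)
        tl = terminal_loop(fold)
        assert tl is not None
        span = (tl[0] - 2, tl[1] + 2)  # overlaps the loop on both sides
        assert assign_arm(fold, span) == "none"
        assert not check_loop_break(fold, span)

    def test_mature_split_across_two_stems_is_none(self):
        rng = np.random.default_rng(5)
        pre, off = _arm_decoy(LET7, rng)
        fold = fold_mfe(pre, STACKING)
        span = (off, off + len(LET7))
        assert assign_arm(fold, span) == "none"
        # ... while staying fully paired: only criterion 1 is violated
        assert check_loop_break(fold, span)

    def test_unpaired_structure_is_none(self):
        fold = fold_mfe("AAAACAACAAAACAACAAAA", STACKING)
        assert fold.pairs == []
        assert assign_arm(fold, (0, 20)) == "none"


class TestStarMismatches:
    def test_perfect_duplex_counts_zero(self):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1)
        fold = fold_mfe(pre, STACKING)
        assert count_star_mismatches(fold, _span_of(pre, LET7)) == 0

    @pytest.mark.parametrize("n_mm", [1, 2, 3])
    def test_planted_mismatches_counted_back(self, n_mm):
        pre = build_hairpin(MIR171, "5p", 6, n_mm, seed=3, stem_ext=10)
        fold = fold_mfe(pre, STACKING)
        assert count_star_mismatches(fold, _span_of(pre, MIR171)) == n_mm

    def test_usage_error_when_not_on_arm(self):
        fold = fold_mfe("AAAACAACAAAACAACAAAA", STACKING)
        with pytest.raises(ValueError):
            count_star_mismatches(fold, (0, 20))


class TestLoopBreak:
    def test_fully_paired_mature_ok(self):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1)
        fold = fold_mfe(pre, STACKING)
        assert check_loop_break(fold, _span_of(pre, LET7))

    def test_five_base_internal_bulge_fails(self):
        rng = np.random.default_rng(4)
        pre, off = _loop_break_decoy(MIR171 + "C", rng)  # 22-mer
        fold = fold_mfe(pre, STACKING)
        span = (off, off + 22)
        assert not check_loop_break(fold, span, max_internal_gap=3)
        # the bulge is 5 nt, so the mismatch rule still passes
        assert count_star_mismatches(fold, span) == 5


class TestMfei:
    @pytest.mark.parametrize("dg,length,gc,amfe,mfei", [
        (50.0, 100, 50.0, 50.0, 1.0),
        (0.0, 421, 40.0, 0.0, 0.0),
        (84.2, 421, 40.0, 20.0, 0.5),
    ])
    def test_arithmetic(self, dg, length, gc, amfe, mfei):
        a, m = compute_mfei(dg, length, gc)
        assert a == pytest.approx(amfe)
        assert m == pytest.approx(mfei)

    @given(st.floats(1.0, 500.0), st.integers(50, 1000), st.floats(1.0, 100.0))
    def test_scale_consistency(self, dg, length, gc):
        a1, m1 = compute_mfei(dg, length, gc)
        a2, m2 = compute_mfei(2 * dg, 2 * length, gc)
        assert a2 == pytest.approx(a1)
        assert m2 == pytest.approx(m1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_mfei(10.0, 0, 50.0)
        with pytest.raises(ValueError):
            compute_mfei(10.0, 100, 0.0)


class TestEvaluate:
    def _eval(self, threshold=0.70):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1, stem_ext=12)
        host = Transcript("t", "GGATTTAGGATTTAGG" + rna_to_dna(pre) + "CCTAAATCCTAAATCC")
        hit = find_homology_hits([host], [MatureRef("let-7", LET7)])[0]
        cand = extract_precursor_window(hit, host)
        fold = fold_mfe(cand.seq, STACKING)
        return evaluate_candidate(cand, fold,
                                  CriteriaThresholds(mfei_threshold=threshold))

    def test_true_precursor_verdict(self):
        ev = self._eval()
        assert ev.verdict
        assert ev.passes == {"arm": True, "mfei": True,
                             "star_mismatch": True, "loop_break": True}

    def test_threshold_monotonicity(self):
        relaxed = self._eval(0.70)
        tight = self._eval(50.0)  # absurdly strict: accepted set can only shrink
        assert relaxed.verdict >= tight.verdict
        assert not tight.verdict


class TestSummarize:
    def test_singleton(self):
        s = summarize_mfei([0.5])
        assert (s.n, s.mean, s.min, s.max) == (1, 0.5, 0.5, 0.5)

    def test_mean_rounding_half_up(self):
        assert summarize_mfei([0.70, 0.81]).mean == 0.76  # 0.755 rounds up

    def test_empty(self):
        s = summarize_mfei([])
        assert s.n == 0 and s.mean is None

    def test_accepts_evaluations(self, mirna_result):
        s = summarize_mfei(mirna_result.accepted)
        assert s.n == len(mirna_result.accepted)
        assert s.min <= s.mean <= s.max
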