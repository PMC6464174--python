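"""Homology screen: deduplication, exact matching, windows, coding filter."""

import numpy as np
import pytest

from mirssr.homology import (
    CoordinateError, MatureRef, Transcript, deduplicate_matures,
    extract_precursor_window, find_homology_hits, flag_coding, parse_family,
)
from mirssr.io import rna_to_dna

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt


def _embed(mature_rna, offset, total=1000, seed=0):
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=total))
    m = rna_to_dna(mature_rna)
    seq = bg[:offset] + m + bg[offset + len(m):]
    return Transcript("t1", seq)


class TestDeduplicate:
    def test_identical_sequences_collapse(self):
        refs = [MatureRef("b-miR1", LET7), MatureRef("a-miR1", LET7)]
        kept = deduplicate_matures(refs)
        assert len(kept) == 1
        assert kept[0].id == "a-miR1"  # lexicographically smallest id wins

    def test_substring_removed_longest_kept(self):
        refs = [MatureRef("long", "UGAGGUAGUAGGUUGUAUAGUU"),
                MatureRef("frag", "GAGGUAGUAGGUUGUAUAGU")]
        kept = deduplicate_matures(refs)
        assert [r.id for r in kept] == ["long"]

    def test_one_mismatch_keeps_both(self):
        refs = [MatureRef("a", LET7), MatureRef("b", LET7[:-1] + "A")]
        assert len(deduplicate_matures(refs)) == 2

    def test_idempotent(self):
        refs = [MatureRef("a", LET7), MatureRef("b", LET7),
                MatureRef("c", LET7[:20])]
        once = deduplicate_matures(refs)
        assert deduplicate_matures(once) == once

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            deduplicate_matures([])


class TestFindHits:
    def test_planted_mature_found_exactly(self):
        tr = _embed(LET7, 250)
        hits = find_homology_hits([tr], [MatureRef("let-7", LET7)])
        assert [(h.t_start, h.t_end, h.match_len) for h in hits] == [(250, 272, 22)]

    def test_single_substitution_kills_hit(self):
        mutated = LET7[:10] + ("A" if LET7[10] != "A" else "C") + LET7[11:]
        tr = _embed(mutated, 250)
        assert find_homology_hits([tr], [MatureRef("let-7", LET7)]) == []

    def test_double_plant_gives_two_hits(self):
        m = rna_to_dna(LET7)
        tr = Transcript("t", "ACGT" * 20 + m + "TTTTGGGG" * 10 + m + "ACGT" * 5)
        hits = find_homology_hits([tr], [MatureRef("let-7", LET7)])
        assert len(hits) == 2
        # agreement with a naive position-by-position scan
        naive = [p for p in range(len(tr.seq) - len(m) + 1)
                 if all(tr.seq[p + q] == m[q] for q in range(len(m)))]
        assert [h.t_start for h in hits] == naive

    def test_short_matures_skipped(self):
        tr = _embed(LET7, 100)
        refs = [MatureRef("short", LET7[:19])]  # < 20 nt: never searched
        assert find_homology_hits([tr], refs, min_len=20) == []

    def test_reverse_strand_optional(self):
        from mirssr.io import revcomp_dna
        m = rna_to_dna(LET7)
        tr = Transcript("t", "CCCC" * 10 + revcomp_dna(m) + "GGGG" * 10)
        assert find_homology_hits([tr], [MatureRef("let-7", LET7)]) == []
        hits = find_homology_hits([tr], [MatureRef("let-7", LET7)],
                                  both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "-"


class TestWindows:
    def test_interior_window_length_421(self):
        tr = _embed(LET7, 250)
        hit = find_homology_hits([tr], [MatureRef("let-7", LET7)])[0]
        cand = extract_precursor_window(hit, tr, flank=200)
        assert (cand.window_start, cand.window_end) == (50, 472)
        assert len(cand.seq) == 422
        assert cand.mature_offset == 200
        assert not cand.truncated
        assert "T" not in cand.seq  # RNA alphabet in the window

    def test_clipping_at_transcript_start(self):
        tr = _embed(LET7, 5)
        hit = find_homology_hits([tr], [MatureRef("let-7", LET7)])[0]
        cand = extract_precursor_window(hit, tr, flank=200)
        assert (cand.window_start, cand.window_end) == (0, 227)
        assert cand.mature_offset == 5
        assert cand.truncated

    def test_window_never_longer_than_two_flanks_plus_match(self):
        tr = _embed(LET7, 600)
        hit = find_homology_hits([tr], [MatureRef("let-7", LET7)])[0]
        cand = extract_precursor_window(hit, tr, flank=200)
        assert cand.window_end - cand.window_start <= 2 * 200 + hit.match_len

    def test_out_of_bounds_hit_is_coordinate_error(self):
        from mirssr.homology import HomologyHit
        tr = _embed(LET7, 250, total=1000)
        bad = HomologyHit("t1", "let-7", 985, 1006, 21)
        with pytest.raises(CoordinateError):
            extract_precursor_window(bad, tr)


class TestCodingFilter:
    def _candidate(self, tr, mature=LET7):
        hit = find_homology_hits([tr], [MatureRef("let-7", mature)])[0]
        return extract_precursor_window(hit, tr)

    def test_planted_orf_flags_window(self):
        rng = np.random.default_rng(3)
        # 150 sense codons with no stops, then the mature right after
        codons = [c for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        orf = "ATG" + "".join(rng.choice(codons[1:], size=149)) + "TAA"
        seq = orf + rna_to_dna(LET7) + "T" * 30
        tr = Transcript("t", seq)
        assert flag_coding(self._candidate(tr), tr, min_orf_aa=100)

    def test_stop_saturated_background_is_noncoding(self):
        # a lattice with stop codons in all six frames leaves no 100-codon ORF
        unit = "TAAATAAATAA" + "TTATTTATTTA"  # fwd stops + rev-strand stops
        seq = unit * 25 + rna_to_dna(LET7) + unit * 3
        tr = Transcript("t", seq)
        cand = self._candidate(tr)
        assert not flag_coding(cand, tr, min_orf_aa=100)

    def test_degenerate_threshold_flags_any_minimal_orf(self):
        seq = "TAATAATAA" + "ATGAAATAA" + rna_to_dna(LET7) + "TAATAATAA"
        tr = Transcript("t", seq)
        assert flag_coding(self._candidate(tr), tr, min_orf_aa=1)


def test_family_parsing():
    assert parse_family("ath-miR319a") == "miR319"
    assert parse_family("vvi-miR828a") == "miR828"
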