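"""The synthetic-transcriptome generator: construction contracts, truth
round-trips, determinism, background composition."""

import json

import numpy as np
import pytest

from mirssr.fold import PAIR_COUNT, STACKING, fold_mfe
from mirssr.homology import MatureRef, find_homology_hits
from mirssr.criteria import terminal_loop
from mirssr.simulate import (
    CANONICAL_MATURES, FixtureConfig, PrecursorPlan, SSRPlan, build_hairpin,
    generate_fixture, standard_fixture_config, truth_rows, write_fixture,
)
from mirssr.ssr import scan_ssrs

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestBuildHairpin:
    def test_perfect_duplex_pairs_every_mature_base(self):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1)
        # base-pair-maximizing model: the duplex region must pair completely
        fold = fold_mfe(pre, PAIR_COUNT)
        pm = fold.pair_map()
        off = pre.find(LET7)
        assert all(off + k in pm for k in range(len(LET7)))

    def test_shortest_legal_hairpin_has_three_nt_loop(self):
        pre = build_hairpin(LET7, "5p", 3, 0, seed=1)
        fold = fold_mfe(pre, STACKING)
        tl = terminal_loop(fold)
        assert tl is not None and tl[1] - tl[0] == 3

    def test_layout_is_arm_loop_arm(self):
        pre = build_hairpin(LET7, "5p", 6, 0, seed=1, stem_ext=0)
        assert len(pre) == 2 * len(LET7) + 6
        assert pre.startswith(LET7)
        pre3 = build_hairpin(LET7, "3p", 6, 0, seed=1, stem_ext=0)
        assert pre3.endswith(LET7)

    def test_deterministic_for_fixed_seed(self):
        assert build_hairpin(LET7, "5p", 6, 3, seed=9) == \
            build_hairpin(LET7, "5p", 6, 3, seed=9)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            build_hairpin("UGAGGUAGXAGGUUGUAUAGUU")       # alphabet
        with pytest.raises(ValueError):
            build_hairpin(LET7, star_mismatches=23)       # > mature length
        with pytest.raises(ValueError):
            build_hairpin(LET7, loop_len=2)
        with pytest.raises(ValueError):
            build_hairpin("UGAGGUAGUAGGUUG")              # < 20 nt


class TestStandardFixture:
    def test_counts(self, std_fixture):
        assert len(std_fixture.transcripts) == 15
        assert len(std_fixture.truth.precursors) == 3
        assert sorted(v for _, v in std_fixture.truth.decoys) == \
            ["arm", "coding", "loop_break", "mfei", "star_mismatch"]
        assert len(std_fixture.truth.ssrs) == 5

    def test_planted_coordinates_inside_hosts(self, std_fixture):
        by_id = {t.id: t for t in std_fixture.transcripts}
        for p in std_fixture.truth.precursors + [d for d, _ in std_fixture.truth.decoys]:
            host = by_id[p.insert_transcript]
            assert 0 <= p.insert_offset < p.insert_offset + p.precursor_len <= len(host)
        for s in std_fixture.truth.ssrs:
            host = by_id[s.insert_transcript]
            assert host.seq[s.insert_offset:s.end] == s.motif * s.repeats

    def test_ssr_truth_round_trip(self, std_fixture):
        found = []
        for tr in std_fixture.transcripts:
            found.extend((l.transcript_id, l.start, l.motif, l.repeats)
                         for l in scan_ssrs(tr))
        planted = [(s.insert_transcript, s.insert_offset, s.motif, s.repeats)
                   for s in std_fixture.truth.ssrs]
        assert sorted(found) == sorted(planted)

    def test_each_mature_occurs_exactly_once(self, std_fixture):
        from mirssr.homology import deduplicate_matures
        matures = deduplicate_matures(std_fixture.matures)
        hits = find_homology_hits(std_fixture.transcripts, matures)
        assert len(hits) == 8  # 3 true + 5 decoys, one hit each

    def test_byte_identical_across_runs(self, std_fixture_paths, tmp_path):
        fx = generate_fixture(seed=7)
        paths = write_fixture(fx, str(tmp_path))
        for key in ("transcripts", "matures", "truth"):
            with open(paths[key], "rb") as a, open(std_fixture_paths[key], "rb") as b:
                assert a.read() == b.read()

    def test_truth_table_payloads_parse(self, std_fixture):
        rows = truth_rows(std_fixture.truth)
        assert len(rows) == 13  # 3 true + 5 decoys + 5 SSRs
        for row in rows:
            payload = json.loads(row[4])
            assert isinstance(payload, dict)
            assert int(row[2]) >= 1  # 1-based starts


class TestCustomConfigs:
    def test_ten_transcripts_eleven_features(self):
        m = CANONICAL_MATURES
        cfg = FixtureConfig(
            precursors=tuple(
                [PrecursorPlan("true", mid, m[mid], host_len=1000)
                 for mid in ("ath-miR319a", "cca-miR396c", "pde-miR159")]
                + [PrecursorPlan("arm", "ath-miR167d", m["ath-miR167d"], host_len=1000),
                   PrecursorPlan("loop_break", "vvi-miR828a", m["vvi-miR828a"],
                                 host_len=1000),
                   PrecursorPlan("star_mismatch", "ctr-miR171", m["ctr-miR171"],
                                 star_mismatches=7, host_len=1000)]),
            ssrs=(SSRPlan("AG", 8, host_len=1000),
                  SSRPlan("AAG", 6, host_len=1000),
                  SSRPlan("AT", 7, host_len=1000),
                  SSRPlan("TCA", 5, host_len=1000, host_group="shared"),
                  SSRPlan("ACCG", 5, host_len=1000, host_group="shared")),
            n_background=0, verify=False)
        fx = generate_fixture(cfg, seed=42)
        assert len(fx.transcripts) == 10
        assert len(truth_rows(fx.truth)) == 11
        assert all(len(t.seq) == 1000 for t in fx.transcripts[:6])

    def test_zero_planted_features_gives_pure_background(self, tmp_path):
        cfg = FixtureConfig(
            precursors=(), ssrs=(), n_background=3, background_len=800,
            extra_refs=(("ath-miR319a", CANONICAL_MATURES["ath-miR319a"]),
                        ("ctr-miR171", CANONICAL_MATURES["ctr-miR171"])))
        fx = generate_fixture(cfg, seed=5)
        paths = write_fixture(fx, str(tmp_path))
        from mirssr.pipeline import run_mirna_pipeline, run_ssr_pipeline
        res = run_mirna_pipeline(paths["transcripts"], paths["matures"])
        assert res.manifest.counts["hits"] == 0
        assert res.accepted == []
        ssr_res = run_ssr_pipeline(paths["transcripts"])
        assert ssr_res.loci == []

    def test_background_gc_within_two_points(self):
        cfg = FixtureConfig(precursors=(), ssrs=(), n_background=3,
                            background_len=2000, background_gc=0.45,
                            extra_refs=(("ath-miR319a",
                                         CANONICAL_MATURES["ath-miR319a"]),),
                            verify=False)
        fx = generate_fixture(cfg, seed=8)
        for tr in fx.transcripts:
            gc = (tr.seq.count("G") + tr.seq.count("C")) / len(tr.seq) * 100
            assert abs(gc - 45.0) <= 2.0

    def test_feature_longer_than_host_is_error(self):
        from mirssr.simulate import FixtureBuildError
        cfg = FixtureConfig(
            precursors=(PrecursorPlan("true", "ath-miR319a",
                                      CANONICAL_MATURES["ath-miR319a"],
                                      stem_ext=30, host_len=80),),
            ssrs=(), n_background=0)
        with pytest.raises(FixtureBuildError):
            generate_fixture(cfg, seed=1)
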