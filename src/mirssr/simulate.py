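"""Synthetic transcriptome fixtures with planted, verifiable ground truth.

The generator emulates the inputs of a de novo assembly mined for conserved
miRNAs and EST-SSRs: short contig-like transcripts carrying

* planted miRNA precursors — hairpins built around a real mature sequence,
  with a controlled number of star-arm mismatches, a controlled terminal
  loop, and an optional GC-rich stem extension below the miRNA:miRNA* duplex
  (as in real pre-miRNAs, where the duplex sits on a longer stem);
* decoy precursors that violate exactly one acceptance criterion each
  (arm / star_mismatch / loop_break / mfei / coding) while satisfying the
  other three;
* SSR loci of unit size 1-6 with primer-friendly flanks; and
* neutral i.i.d. background sequence of configurable GC.

Every planted feature is *verified at generation time* by running the actual
screening, folding and evaluation operations; random draws are retried (still
deterministically, from a single seeded stream) until the construction meets
its contract.  Identical (config, seed) therefore always yields byte-identical
FASTA and truth tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import criteria as crit
from . import homology as hom
from . import primers as prm
from . import ssr as ssrmod
from .fold import STACKING, fold_mfe
from .io import revcomp_rna, rna_to_dna, write_fasta

RNA = frozenset("ACGU")

#: star-arm bases that cannot pair a given mature base (G-U wobble included)
_NONPAIRING = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}


class FixtureBuildError(RuntimeError):
    """A planted feature could not be built to contract within the retry budget."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPrecursor:
    family_name: str
    mature_seq: str          # RNA, 20-24 nt
    arm: str                 # 5p | 3p
    loop_len: int
    star_mismatches: int
    insert_transcript: str
    insert_offset: int       # 0-based start of the precursor in its host
    precursor_len: int = 0
    mature_start: int = 0    # 0-based, host coordinates
    mature_end: int = 0


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    repeats: int
    insert_transcript: str
    insert_offset: int

    @property
    def end(self) -> int:
        return self.insert_offset + len(self.motif) * self.repeats


@dataclass
class FixtureTruth:
    precursors: List[PlantedPrecursor]
    decoys: List[Tuple[PlantedPrecursor, str]]  # (precursor, violated criterion)
    ssrs: List[PlantedSSR]
    seed: int


@dataclass
class Fixture:
    transcripts: List[hom.Transcript]
    matures: List[hom.MatureRef]
    truth: FixtureTruth


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

VIOLATIONS = ("arm", "star_mismatch", "loop_break", "mfei", "coding")


@dataclass(frozen=True)
class PrecursorPlan:
    """One planted hairpin. ``kind`` is ``true`` or a violated criterion."""

    kind: str
    mature_id: str
    mature_seq: str
    arm: str = "5p"
    loop_len: int = 6
    star_mismatches: int = 0
    stem_ext: int = 12
    host_len: int = 230

    def __post_init__(self):
        if self.kind not in ("true",) + VIOLATIONS:
            raise ValueError(f"unknown precursor plan kind {self.kind!r}")
        if self.arm not in ("5p", "3p"):
            raise ValueError("arm must be 5p or 3p")


@dataclass(frozen=True)
class SSRPlan:
    motif: str
    repeats: int
    host_len: int = 600
    flank_gc: float = 0.50
    design_primers: bool = True
    host_group: Optional[str] = None  # plans sharing a group share a host


@dataclass(frozen=True)
class FixtureConfig:
    precursors: Tuple[PrecursorPlan, ...] = ()
    ssrs: Tuple[SSRPlan, ...] = ()
    n_background: int = 2
    background_len: int = 1000
    background_gc: float = 0.45
    extra_refs: Tuple[Tuple[str, str], ...] = ()
    verify: bool = True
    max_retries: int = 200


# the default mature reference set: canonical conserved plant miRNAs
# (miRBase-style ids) plus one synthetic A/U-rich mature used by the MFEI
# decoy (labelled syn-*; it is a constructed stand-in, not a miRBase entry)
CANONICAL_MATURES: Dict[str, str] = {
    "ath-miR319a": "UUGGACUGAAGGGAGCUCCCU",
    "cca-miR396c": "UUCAAGAAAGCUGUGGGAAAA",
    "pde-miR159": "UUUGGUUUGAAGGGAGCUCUA",
    "ath-miR167d": "UGAAGCUGCCAGCAUGAUCUGG",
    "ctr-miR171": "UUGAGCCGCGUCAAUAUCUCC",
    "vvi-miR828a": "UCUUGCUCAAAUGAGUAUUCCA",
    "mes-miR477h": "ACUCUCCCUCAAGGGCUUCAG",
    "sly-miR4376": "ACGCAGGAGAGAUGAUGCUGGA",
    "syn-miR9001": "UAUUAAUUAUAUAAUUAAUAUU",
}


def standard_fixture_config() -> FixtureConfig:
    """The standard study-condition fixture: 3 true precursors, 5 decoys
    (one per violated criterion), 5 SSR loci, 2 background transcripts."""
    return FixtureConfig(
        precursors=(
            PrecursorPlan("true", "ath-miR319a", CANONICAL_MATURES["ath-miR319a"],
                          arm="5p", star_mismatches=0, stem_ext=12),
            PrecursorPlan("true", "cca-miR396c", CANONICAL_MATURES["cca-miR396c"],
                          arm="3p", star_mismatches=1, stem_ext=14),
            PrecursorPlan("true", "pde-miR159", CANONICAL_MATURES["pde-miR159"],
                          arm="5p", star_mismatches=2, stem_ext=14),
            PrecursorPlan("arm", "ath-miR167d", CANONICAL_MATURES["ath-miR167d"],
                          stem_ext=20),
            PrecursorPlan("star_mismatch", "ctr-miR171", CANONICAL_MATURES["ctr-miR171"],
                          star_mismatches=7, stem_ext=20),
            PrecursorPlan("loop_break", "vvi-miR828a", CANONICAL_MATURES["vvi-miR828a"],
                          stem_ext=16),
            PrecursorPlan("mfei", "syn-miR9001", CANONICAL_MATURES["syn-miR9001"],
                          host_len=260),
            PrecursorPlan("coding", "mes-miR477h", CANONICAL_MATURES["mes-miR477h"],
                          stem_ext=30),
        ),
        ssrs=(
            SSRPlan("AG", 8),
            SSRPlan("AAG", 6),
            SSRPlan("AT", 7),
            SSRPlan("TCA", 5),
            SSRPlan("ACCG", 5),
        ),
        extra_refs=(
            ("osa-miR319a-dup", CANONICAL_MATURES["ath-miR319a"]),
            ("xxx-miR159-frag", CANONICAL_MATURES["pde-miR159"][:20]),
            ("sly-miR4376", CANONICAL_MATURES["sly-miR4376"]),
        ),
    )


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _unpairable_flank(rng: np.random.Generator, n: int, c_frac: float = 0.55) -> str:
    """A/C-only DNA: cannot base-pair internally (no G/T), so it dilutes a
    window's folding energy without adding structure."""
    return "".join(rng.choice(list("AC"), size=n, p=[1 - c_frac, c_frac]))


def _loop_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("CA"), size=n, p=[0.7, 0.3]))


def _gc_rich(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("GC"), size=n))


def _star_arm(mature: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Reverse complement of the mature with the given mature positions
    substituted so they cannot pair (wobble pairs counted as pairing)."""
    star = list(revcomp_rna(mature))
    L = len(mature)
    for p in positions:
        choices = _NONPAIRING[mature[p]]
        star[L - 1 - p] = choices[int(rng.integers(len(choices)))]
    return "".join(star)


def _pick_mismatch_positions(rng: np.random.Generator, mature_len: int,
                             count: int, max_run: int = 3) -> List[int]:
    """Mismatch positions in the mature interior with no run longer than
    ``max_run`` (so only the intended criterion is stressed)."""
    if count == 0:
        return []
    lo, hi = 2, mature_len - 3  # keep duplex ends clamped
    for _ in range(500):
        pos = sorted(rng.choice(np.arange(lo, hi + 1), size=count, replace=False).tolist())
        runs, run = [], [pos[0]]
        ok = True
        for p in pos[1:]:
            if p == run[-1] + 1:
                run.append(p)
            elif p == run[-1] + 2:
                # a lone paired base between bulges gains no stacking and
                # would stay unpaired, silently growing the mismatch count
                ok = False
                break
            else:
                runs.append(run)
                run = [p]
        runs.append(run)
        if ok and max(len(r) for r in runs) <= max_run:
            return pos
    raise FixtureBuildError("could not place mismatch positions")


def build_hairpin(mature_seq: str, arm: str = "5p", loop_len: int = 6,
                  star_mismatches: int = 0, seed: int = 0, *,
                  rng: Optional[np.random.Generator] = None,
                  mismatch_positions: Optional[Sequence[int]] = None,
                  stem_ext: int = 0) -> str:
    """Construct a hairpin precursor (RNA): 5' arm + terminal loop + 3' arm.

    The mature sits on the declared arm; the star arm is its reverse
    complement with ``star_mismatches`` positions substituted to non-pairing
    bases.  ``stem_ext`` adds a GC-rich closing stem below the duplex.
    Deterministic for a fixed seed.
    """
    mature = mature_seq.upper().replace("T", "U")
    if set(mature) - RNA:
        raise ValueError("mature sequence must be A/C/G/U")
    if not 20 <= len(mature) <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if star_mismatches > len(mature):
        raise ValueError("star_mismatches exceeds mature length")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be 5p or 3p")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mismatch_positions is None:
        mismatch_positions = _pick_mismatch_positions(rng, len(mature), star_mismatches) \
            if star_mismatches else []
    if len(mismatch_positions) != star_mismatches:
        raise ValueError("mismatch_positions inconsistent with star_mismatches")
    star = _star_arm(mature, mismatch_positions, rng)
    loop = _loop_seq(rng, loop_len)
    ext5 = _gc_rich(rng, stem_ext)
    ext3 = revcomp_rna(ext5)
    if arm == "5p":
        return ext5 + mature + loop + star + ext3
    return ext5 + star + loop + mature + ext3


def _hairpin_mature_offset(plan: PrecursorPlan, precursor_len: int) -> int:
    m = len(plan.mature_seq)
    if plan.arm == "5p":
        return plan.stem_ext
    # 3p: ext + star + loop + mature; star has the same length as the mature
    return precursor_len - plan.stem_ext - m


def _arm_decoy(mature: str, rng: np.random.Generator, enclose: int = 20,
               split: int = 12, loop_len: int = 5) -> Tuple[str, int]:
    """A precursor whose MFE fold pairs the mature into two different stems:
    the mature is fully paired (no loop/break, zero star mismatches) yet sits
    on no single hairpin arm.  Returns (precursor RNA, mature offset)."""
    left, right = mature[:split], mature[split:]
    core = (revcomp_rna(left) + _loop_seq(rng, loop_len) + left
            + right + _loop_seq(rng, loop_len) + revcomp_rna(right))
    enc = _gc_rich(rng, enclose)
    pre = enc + core + revcomp_rna(enc)
    offset = enclose + len(left) + loop_len
    return pre, offset


def _loop_break_decoy(mature: str, rng: np.random.Generator, bulge: Tuple[int, int] = (9, 14),
                      loop_len: int = 6, stem_ext: int = 16) -> Tuple[str, int]:
    """Mature with an internal ``bulge`` (5 unpaired bases by default: passes
    the <=6 mismatch rule but breaks the no-gap>3 rule)."""
    a, b = bulge
    star = revcomp_rna(mature[:a] + mature[b:])
    ext5 = _gc_rich(rng, stem_ext)
    pre = ext5 + mature + _loop_seq(rng, loop_len) + star + revcomp_rna(ext5)
    return pre, stem_ext


def _mfei_decoy(mature: str, rng: np.random.Generator, loop_len: int = 6) -> Tuple[str, int]:
    """A perfect but A/U-only (thermodynamically weak) duplex with no stem
    extension: structurally a clean hairpin, but the window's MFEI stays far
    below the acceptance threshold once diluted by unpairable flanks."""
    pre = mature + _loop_seq(rng, loop_len) + revcomp_rna(mature)
    return pre, 0


def _orf_dna(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) A/G-only codons (stop-free by construction) + TAA."""
    body = "".join(rng.choice(list("AG"), size=3 * (n_codons - 2)))
    return "ATG" + body + "TAA"


# ---------------------------------------------------------------------------
# host assembly and verification
# ---------------------------------------------------------------------------

_DEFAULT_THRESHOLDS = crit.CriteriaThresholds()


def _expected_passes(kind: str) -> Dict[str, bool]:
    expected = {"arm": True, "mfei": True, "star_mismatch": True, "loop_break": True}
    if kind in expected:
        expected[kind] = False
    return expected


def _build_precursor_host(plan: PrecursorPlan, rng: np.random.Generator,
                          background_gc: float) -> Tuple[str, int, int]:
    """(host DNA, precursor offset, precursor length) for one plan."""
    if plan.kind == "arm":
        pre, _ = _arm_decoy(plan.mature_seq, rng, enclose=plan.stem_ext)
    elif plan.kind == "loop_break":
        pre, _ = _loop_break_decoy(plan.mature_seq, rng, stem_ext=plan.stem_ext)
    elif plan.kind == "mfei":
        pre, _ = _mfei_decoy(plan.mature_seq, rng)
    else:  # true, star_mismatch, coding: a regular hairpin
        pre = build_hairpin(plan.mature_seq, plan.arm, plan.loop_len,
                            plan.star_mismatches, rng=rng, stem_ext=plan.stem_ext)
    pre_dna = rna_to_dna(pre)
    if plan.kind == "coding":
        orf = _orf_dna(rng, 151)
        tail = _random_dna(rng, 60, background_gc)
        host = orf + pre_dna + tail
        return host, len(orf), len(pre_dna)
    room = plan.host_len - len(pre_dna)
    if room < 4:
        raise FixtureBuildError(
            f"host_len {plan.host_len} too short for precursor of {len(pre_dna)} nt")
    left = room // 2
    if plan.kind == "mfei":
        host = (_unpairable_flank(rng, left) + pre_dna
                + _unpairable_flank(rng, room - left))
    else:
        host = (_random_dna(rng, left, background_gc) + pre_dna
                + _random_dna(rng, room - left, background_gc))
    return host, left, len(pre_dna)


def _verify_precursor_host(plan: PrecursorPlan, host: str, tid: str) -> bool:
    """Run the real screen on one host and check the plan's contract."""
    tr = hom.Transcript(tid, host)
    mat = hom.MatureRef(plan.mature_id, plan.mature_seq)
    hits = hom.find_homology_hits([tr], [mat])
    if len(hits) != 1:
        return False
    if ssrmod.scan_ssrs(tr):  # no incidental microsatellites in miRNA hosts
        return False
    cand = hom.extract_precursor_window(hits[0], tr)
    coding = hom.flag_coding(cand, tr)
    if coding != (plan.kind == "coding"):
        return False
    ev = crit.evaluate_candidate(cand, fold_mfe(cand.seq, STACKING), _DEFAULT_THRESHOLDS)
    if ev.passes != _expected_passes(plan.kind):
        return False
    if plan.kind in ("true", "star_mismatch") and ev.star_mismatches != plan.star_mismatches:
        return False
    if plan.kind == "true" and ev.arm != plan.arm:
        return False
    return True


def _build_ssr_host(plans: Sequence[SSRPlan], rng: np.random.Generator
                    ) -> Tuple[str, List[int]]:
    """Host with one or more SSR runs planted at evenly spaced offsets."""
    host_len = plans[0].host_len
    runs = [p.motif.upper() * p.repeats for p in plans]
    total_run = sum(len(r) for r in runs)
    gaps = len(runs) + 1
    pad = host_len - total_run
    if pad < gaps * 30:
        raise FixtureBuildError("SSR host too short for primer-sized flanks")
    seg = pad // gaps
    parts: List[str] = []
    offsets: List[int] = []
    pos = 0
    for k, run in enumerate(runs):
        flank = seg if k < gaps - 1 else pad - seg * (gaps - 1)
        chunk = _random_dna(rng, seg, plans[k].flank_gc)
        parts.append(chunk)
        pos += len(chunk)
        offsets.append(pos)
        parts.append(run)
        pos += len(run)
    parts.append(_random_dna(rng, pad - seg * (gaps - 1), plans[-1].flank_gc))
    return "".join(parts), offsets


def _verify_ssr_host(plans: Sequence[SSRPlan], host: str, offsets: List[int],
                     tid: str) -> bool:
    tr = hom.Transcript(tid, host)
    found = ssrmod.scan_ssrs(tr)
    expected = sorted(
        (off, p.motif.upper(), p.repeats) for off, p in zip(offsets, plans))
    got = sorted((l.start, l.motif, l.repeats) for l in found)
    if got != expected:
        return False
    for loc, p in zip(sorted(found, key=lambda l: l.start), plans):
        if p.design_primers and not prm.design_primer_pairs(tr, loc):
            return False
    return True


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_fixture(config: FixtureConfig | None = None, seed: int = 0) -> Fixture:
    """Build the synthetic transcriptome.  Deterministic: identical
    (config, seed) yields identical transcripts, references and truth."""
    if config is None:
        config = standard_fixture_config()
    rng = np.random.default_rng(seed)
    transcripts: List[hom.Transcript] = []
    precursors: List[PlantedPrecursor] = []
    decoys: List[Tuple[PlantedPrecursor, str]] = []
    ssrs: List[PlantedSSR] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"contig_{counter:04d}"

    for plan in config.precursors:
        tid = next_id()
        for attempt in range(config.max_retries):
            host, offset, pre_len = _build_precursor_host(plan, rng,
                                                          config.background_gc)
            if not config.verify or _verify_precursor_host(plan, host, tid):
                break
        else:
            raise FixtureBuildError(
                f"{plan.kind} precursor {plan.mature_id}: no valid construction "
                f"in {config.max_retries} attempts")
        tr = hom.Transcript(tid, host)
        transcripts.append(tr)
        m_in_pre = host.find(rna_to_dna(plan.mature_seq), offset)
        planted = PlantedPrecursor(
            family_name=hom.parse_family(plan.mature_id),
            mature_seq=plan.mature_seq, arm=plan.arm, loop_len=plan.loop_len,
            star_mismatches=plan.star_mismatches, insert_transcript=tid,
            insert_offset=offset, precursor_len=pre_len,
            mature_start=m_in_pre, mature_end=m_in_pre + len(plan.mature_seq),
        )
        if plan.kind == "true":
            precursors.append(planted)
        else:
            decoys.append((planted, plan.kind))

    # group SSR plans sharing a host
    groups: List[List[SSRPlan]] = []
    by_group: Dict[str, List[SSRPlan]] = {}
    for plan in config.ssrs:
        if plan.host_group is None:
            groups.append([plan])
        else:
            by_group.setdefault(plan.host_group, []).append(plan)
    groups.extend(by_group.values())
    for plans in groups:
        tid = next_id()
        for attempt in range(config.max_retries):
            host, offsets = _build_ssr_host(plans, rng)
            if not config.verify or _verify_ssr_host(plans, host, offsets, tid):
                break
        else:
            raise FixtureBuildError(
                f"SSR host {[p.motif for p in plans]}: no valid construction "
                f"in {config.max_retries} attempts")
        transcripts.append(hom.Transcript(tid, host))
        for off, p in zip(offsets, plans):
            ssrs.append(PlantedSSR(p.motif.upper(), p.repeats, tid, off))

    matures = [hom.MatureRef(p.mature_id, p.mature_seq) for p in config.precursors]
    mature_dna = [rna_to_dna(m.seq) for m in matures]
    for _ in range(config.n_background):
        tid = next_id()
        for attempt in range(config.max_retries):
            host = _random_dna(rng, config.background_len, config.background_gc)
            tr = hom.Transcript(tid, host)
            if config.background_len >= 1000:
                gc = (host.count("G") + host.count("C")) / len(host)
                if abs(gc - config.background_gc) > 0.015:  # keep GC on target
                    continue
            if not config.verify:
                break
            if ssrmod.scan_ssrs(tr):
                continue
            if any(md in host for md in mature_dna):
                continue
            break
        else:
            raise FixtureBuildError("background transcript rejection budget exhausted")
        transcripts.append(hom.Transcript(tid, host))

    for rid, rseq in config.extra_refs:
        matures.append(hom.MatureRef(rid, rseq))

    return Fixture(transcripts=transcripts, matures=matures,
                   truth=FixtureTruth(precursors, decoys, ssrs, seed))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

TRUTH_HEADER = ["feature_type", "transcript_id", "start", "end", "payload"]


def truth_rows(truth: FixtureTruth) -> List[List[str]]:
    rows: List[List[str]] = []
    for p in truth.precursors:
        rows.append(_precursor_row("precursor", p, {}))
    for p, violated in truth.decoys:
        rows.append(_precursor_row("decoy", p, {"violates": violated}))
    for s in truth.ssrs:
        payload = {"motif": s.motif, "repeats": s.repeats}
        rows.append(["ssr", s.insert_transcript, str(s.insert_offset + 1),
                     str(s.end), json.dumps(payload, sort_keys=True)])
    return rows


def _precursor_row(ftype: str, p: PlantedPrecursor, extra: Dict) -> List[str]:
    payload = {
        "family": p.family_name, "mature_seq": p.mature_seq, "arm": p.arm,
        "loop_len": p.loop_len, "star_mismatches": p.star_mismatches,
        "mature_start": p.mature_start + 1, "mature_end": p.mature_end,
    }
    payload.update(extra)
    return [ftype, p.insert_transcript, str(p.insert_offset + 1),
            str(p.insert_offset + p.precursor_len), json.dumps(payload, sort_keys=True)]


def write_fixture(fixture: Fixture, outdir: str) -> Dict[str, str]:
    """Write transcripts.fasta, matures.fasta and truth.tsv; returns paths."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "transcripts": os.path.join(outdir, "transcripts.fasta"),
        "matures": os.path.join(outdir, "matures.fasta"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(paths["transcripts"], [(t.id, t.seq) for t in fixture.transcripts])
    write_fasta(paths["matures"], [(m.id, m.seq) for m in fixture.matures])
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(TRUTH_HEADER) + "\n")
        for row in truth_rows(fixture.truth):
            fh.write("\t".join(row) + "\n")
    return paths
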