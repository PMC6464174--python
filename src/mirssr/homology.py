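"""Homology screen: reference deduplication, exact mature-miRNA matching,
precursor-window extraction and an ORF-based protein-coding filter.

Matching is exact-substring on purpose: a conserved-miRNA screen that demands
zero mismatches, zero gaps and an alignment length of at least 20 nt accepts
exactly the transcripts containing the mature sequence verbatim, so a seeded
aligner (and its e-value machinery) adds nothing but a dependency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Tuple

from .io import dna_to_rna, revcomp_dna, rna_to_dna

DNA_ALPHABET = frozenset("ACGTN")
_FAMILY_RE = re.compile(r"(mir|let|lin)-?(\d+)", re.IGNORECASE)


class CoordinateError(ValueError):
    """A hit or window does not lie inside its host transcript."""


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript (contig surrogate), DNA alphabet."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"transcript {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureRef:
    """A mature miRNA reference with a miRBase-style id (e.g. ath-miR319a)."""

    id: str
    seq: str
    family: str = ""

    def __post_init__(self):
        seq = self.seq.upper().replace("T", "U")
        if not 18 <= len(seq) <= 26:
            raise ValueError(f"mature {self.id!r}: length {len(seq)} outside 18-26 nt")
        bad = set(seq) - frozenset("ACGU")
        if bad:
            raise ValueError(f"mature {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)
        if not self.family:
            object.__setattr__(self, "family", parse_family(self.id))


def parse_family(mature_id: str) -> str:
    """Family label from a miRBase-style id: ``ath-miR319a`` -> ``miR319``."""
    m = _FAMILY_RE.search(mature_id)
    if m:
        return f"miR{m.group(2)}"
    return mature_id


@dataclass(frozen=True)
class HomologyHit:
    """An exact, full-length occurrence of a mature miRNA in a transcript."""

    transcript_id: str
    mature_id: str
    t_start: int  # 0-based half-open transcript coordinates
    t_end: int
    match_len: int
    strand: str = "+"

    def __post_init__(self):
        if self.match_len != self.t_end - self.t_start:
            raise ValueError("match_len inconsistent with coordinates")
        if self.match_len < 1:
            raise ValueError("empty hit")


@dataclass
class PrecursorCandidate:
    """A precursor window cut around a homology hit (RNA alphabet)."""

    hit: HomologyHit
    window_start: int
    window_end: int
    seq: str  # RNA
    mature_offset: int
    coding_flag: bool = False
    truncated: bool = False

    @property
    def mature_len(self) -> int:
        return self.hit.match_len

    @property
    def mature_span(self) -> Tuple[int, int]:
        return (self.mature_offset, self.mature_offset + self.mature_len)


def deduplicate_matures(refs: List[MatureRef]) -> List[MatureRef]:
    """Remove redundant references at 100% identity.

    A reference is dropped when its sequence is identical to, or a full-length
    substring of, another retained reference.  Retention tie-break: keep the
    longest sequence; among equal sequences keep the lexicographically
    smallest id.  Idempotent.
    """
    if not refs:
        raise ValueError("deduplicate_matures: empty reference list")
    # longest first, then smallest id, so keepers are seen before their substrings
    ordered = sorted(refs, key=lambda r: (-len(r.seq), r.id))
    kept: List[MatureRef] = []
    for ref in ordered:
        if any(ref.seq in k.seq for k in kept):
            continue
        kept.append(ref)
    kept.sort(key=lambda r: r.id)
    return kept


def _occurrences(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1


def find_homology_hits(transcripts: List[Transcript], matures: List[MatureRef],
                       min_len: int = 20, both_strands: bool = False) -> List[HomologyHit]:
    """All exact occurrences of each mature (length >= ``min_len``) in each
    transcript, forward strand by default; sorted by (transcript_id, t_start).

    With ``both_strands`` the reverse complement is searched too and hits are
    reported with ``strand='-'`` in reverse-complement coordinates.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    hits: List[HomologyHit] = []
    usable = [m for m in matures if len(m.seq) >= min_len]
    for tr in transcripts:
        strands = [("+", tr.seq)]
        if both_strands:
            strands.append(("-", revcomp_dna(tr.seq)))
        for strand, seq in strands:
            for mat in usable:
                needle = rna_to_dna(mat.seq)
                for pos in _occurrences(seq, needle):
                    hits.append(HomologyHit(tr.id, mat.id, pos, pos + len(needle),
                                            len(needle), strand))
    hits.sort(key=lambda h: (h.transcript_id, h.t_start, h.strand, h.mature_id))
    return hits


def extract_precursor_window(hit: HomologyHit, transcript: Transcript,
                             flank: int = 200) -> PrecursorCandidate:
    """Cut the putative precursor window: ``flank`` nt upstream of the mature
    to ``flank`` nt downstream, clipped at the transcript ends.

    Clipped windows proceed but carry ``truncated=True``.
    """
    seq = transcript.seq if hit.strand == "+" else revcomp_dna(transcript.seq)
    if hit.transcript_id != transcript.id:
        raise CoordinateError(f"hit transcript {hit.transcript_id!r} != {transcript.id!r}")
    if not (0 <= hit.t_start < hit.t_end <= len(seq)):
        raise CoordinateError(
            f"hit [{hit.t_start},{hit.t_end}) outside transcript {transcript.id!r} "
            f"of length {len(seq)}")
    mature_dna = seq[hit.t_start:hit.t_end]
    ws = max(0, hit.t_start - flank)
    we = min(len(seq), hit.t_end + flank)
    return PrecursorCandidate(
        hit=hit,
        window_start=ws,
        window_end=we,
        seq=dna_to_rna(seq[ws:we]),
        mature_offset=hit.t_start - ws,
        truncated=(hit.t_start < flank) or (hit.t_end + flank > len(seq)),
    )


# --- protein-coding filter -------------------------------------------------

_STOPS = frozenset({"TAA", "TAG", "TGA"})


def _orfs_one_strand(seq: str, min_codons: int):
    """Yield (start, end) DNA intervals (0-based half-open, this strand) of
    ORFs >= min_codons: ATG-to-stop, or open-ended at a sequence boundary."""
    n = len(seq)
    for frame in range(3):
        orf_start: Optional[int] = frame  # open 5' end at the boundary
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos:pos + 3]
            if codon in _STOPS:
                if orf_start is not None and (pos - orf_start) // 3 >= min_codons:
                    yield (orf_start, pos)
                orf_start = None
            elif orf_start is None and codon == "ATG":
                orf_start = pos
            pos += 3
        if orf_start is not None and (n - orf_start) // 3 >= min_codons:
            yield (orf_start, n)  # open 3' end


def find_orfs(transcript: Transcript, min_codons: int = 100) -> List[Tuple[int, int, str]]:
    """ORFs >= ``min_codons`` in all six frames, as (start, end, strand)
    intervals in forward-transcript coordinates."""
    n = len(transcript)
    out: List[Tuple[int, int, str]] = []
    for a, b in _orfs_one_strand(transcript.seq, min_codons):
        out.append((a, b, "+"))
    for a, b in _orfs_one_strand(revcomp_dna(transcript.seq), min_codons):
        out.append((n - b, n - a, "-"))
    return sorted(out)


def flag_coding(candidate: PrecursorCandidate, transcript: Transcript,
                min_orf_aa: int = 100) -> bool:
    """True iff the precursor window overlaps an ORF of >= ``min_orf_aa``
    codons in any of the six frames of the host transcript."""
    n = len(transcript)
    if candidate.hit.strand == "+":
        ws, we = candidate.window_start, candidate.window_end
    else:  # window coordinates live in reverse-complement space
        ws, we = n - candidate.window_end, n - candidate.window_start
    for a, b, _strand in find_orfs(transcript, min_orf_aa):
        if a < we and ws < b:
            return True
    return False


def set_coding_flags(candidates: List[PrecursorCandidate],
                     transcripts_by_id: dict, min_orf_aa: int = 100) -> None:
    for cand in candidates:
        cand.coding_flag = flag_coding(cand, transcripts_by_id[cand.hit.transcript_id],
                                       min_orf_aa)
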