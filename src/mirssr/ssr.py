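"""MISA-style microsatellite (EST-SSR) detection and statistics.

Loci are maximal tandem runs of a primitive 1-6 nt unit meeting per-unit
minimum repeat counts (defaults 10, 6, 5, 5, 5, 5 for mono- through
hexanucleotides).  Motifs are summarized by canonical class — the
lexicographically smallest string over all cyclic rotations of the motif and
of its reverse complement, the usual "AG/CT", "AAG/CTT" notation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .homology import Transcript
from .io import revcomp_dna

#: minimum repeat count by unit length (MISA-style)
DEFAULT_MIN_REPEATS: Dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRLocus:
    transcript_id: str
    motif: str        # primitive unit, as read from the sequence
    unit_len: int
    repeats: int
    start: int        # 0-based half-open; reports use 1-based inclusive
    end: int
    compound_id: Optional[str] = None

    def __post_init__(self):
        if self.end - self.start != self.unit_len * self.repeats:
            raise ValueError("SSR span inconsistent with unit_len x repeats")


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a tandem of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def scan_ssrs(transcript: Transcript,
              thresholds: Dict[int, int] | None = None) -> List[SSRLocus]:
    """All maximal tandem runs meeting the per-unit thresholds.

    A run is attributed to its primitive unit only (no (ATAT)n where (AT)2n
    applies), and a locus wholly contained in another locus's span is a
    sub-run and is dropped.  Sorted by start, then unit length.
    """
    thr = dict(DEFAULT_MIN_REPEATS if thresholds is None else thresholds)
    s = transcript.seq
    n = len(s)
    raw: List[SSRLocus] = []
    for u, min_rep in sorted(thr.items()):
        i = 0
        while i + 2 * u <= n:
            motif = s[i:i + u]
            if "N" in motif or not is_primitive(motif) or s[i + u:i + 2 * u] != motif:
                i += 1
                continue
            k = 2
            while s[i + k * u:i + (k + 1) * u] == motif:
                k += 1
            if k >= min_rep:
                raw.append(SSRLocus(transcript.id, motif, u, k, i, i + k * u))
                i += (k - 1) * u + 1  # skip rotated restatements of this run
            else:
                i += 1
    # drop sub-runs: loci wholly contained in a strictly larger locus
    kept = [
        loc for loc in raw
        if not any(o is not loc and o.start <= loc.start and loc.end <= o.end
                   and (o.end - o.start) > (loc.end - loc.start)
                   for o in raw)
    ]
    kept.sort(key=lambda l: (l.start, l.unit_len))
    return kept


@dataclass(frozen=True)
class MotifClass:
    representative: str
    members: tuple

    def __str__(self) -> str:  # field notation, e.g. "AG/CT"
        rc = revcomp_dna(self.representative)
        return f"{self.representative}/{rc}"


def _rotations(motif: str) -> List[str]:
    return [motif[k:] + motif[:k] for k in range(len(motif))]


def canonical_motif_class(motif: str) -> MotifClass:
    """Canonical class of a primitive motif under rotation and reverse
    complement; the representative is the lexicographic minimum member."""
    motif = motif.upper().replace("U", "T")
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif must be 1-6 nt")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    members = sorted(set(_rotations(motif)) | set(_rotations(revcomp_dna(motif))))
    return MotifClass(representative=members[0], members=tuple(members))


def merge_compound(loci: Sequence[SSRLocus],
                   max_interruption: int = 100) -> List[SSRLocus]:
    """Group loci of one transcript separated by <= ``max_interruption`` nt
    under a shared compound id; singleton groups keep ``compound_id=None``."""
    loci = sorted(loci, key=lambda l: (l.start, l.unit_len))
    groups: List[List[SSRLocus]] = []
    for loc in loci:
        if groups and loc.start - groups[-1][-1].end <= max_interruption:
            groups[-1].append(loc)
        else:
            groups.append([loc])
    out: List[SSRLocus] = []
    cnum = 0
    for grp in groups:
        if len(grp) == 1:
            out.append(grp[0])
        else:
            cnum += 1
            cid = f"{grp[0].transcript_id}.c{cnum}"
            out.extend(replace(l, compound_id=cid) for l in grp)
    return out


def ssr_summary(loci: Sequence[SSRLocus], exclude_mono: bool = True) -> pd.DataFrame:
    """Distribution table: counts and percentages by unit length and by
    canonical motif class.  Mononucleotide loci are excluded by default
    (unreliable under sequencing/assembly error)."""
    use = [l for l in loci if not (exclude_mono and l.unit_len == 1)]
    rows = []
    if use:
        unit_names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
        total = len(use)
        by_unit: Dict[int, int] = {}
        by_class: Dict[str, int] = {}
        for l in use:
            by_unit[l.unit_len] = by_unit.get(l.unit_len, 0) + 1
            cls = str(canonical_motif_class(l.motif))
            by_class[cls] = by_class.get(cls, 0) + 1
        for u in sorted(by_unit):
            rows.append(("unit", unit_names[u], by_unit[u], 100.0 * by_unit[u] / total))
        for cls in sorted(by_class):
            rows.append(("motif_class", cls, by_class[cls], 100.0 * by_class[cls] / total))
    return pd.DataFrame(rows, columns=["level", "label", "count", "percent"])
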