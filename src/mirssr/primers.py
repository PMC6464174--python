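"""Nearest-neighbor melting temperatures and SSR-flanking primer design.

Tm uses the unified SantaLucia (1998) nearest-neighbor DNA parameter set with
the entropy salt correction 0.368 * (N-1) * ln[Na+] and a primer-excess total
strand concentration (CT/4 term).  Defaults: 50 mM monovalent cation, 50 nM
oligo — stated explicitly because NN Tm values are meaningless without them.

Primer pairs flank (never overlap) the SSR run, obey the marker-design
constraints (length 18-25 nt, Tm 55-62 degC, product 100-300 bp) and are
ranked by closeness of the pair's mean Tm to the 57 degC optimum, then by the
Tm difference between the two primers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .homology import Transcript
from .io import revcomp_dna
from .ssr import SSRLocus

log = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (mol K)

# Unified SantaLucia 1998 NN parameters: dH (kcal/mol), dS (cal/mol/K),
# keyed by the top-strand 5'->3' dinucleotide.
_NN: Dict[str, Tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # per terminal G/C
_INIT_AT = (2.3, 4.1)    # per terminal A/T
_SYM_DS = -1.4           # self-complementary symmetry correction


def melt_tm(oligo: str, monovalent_mm: float = 50.0, oligo_nm: float = 50.0) -> float:
    """Duplex melting temperature (degC) of a DNA oligo with its perfect
    complement under the stated salt and strand concentrations."""
    s = oligo.upper()
    if not 10 <= len(s) <= 40:
        raise ValueError("oligo length must be 10-40 nt")
    if set(s) - set("ACGT"):
        raise ValueError("oligo must be A/C/G/T only")
    if monovalent_mm <= 0 or oligo_nm <= 0:
        raise ValueError("concentrations must be positive")
    dh = 0.0
    ds = 0.0
    for k in range(len(s) - 1):
        h, sv = _NN[s[k:k + 2]]
        dh += h
        ds += sv
    for term in (s[0], s[-1]):
        h, sv = _INIT_GC if term in "GC" else _INIT_AT
        dh += h
        ds += sv
    selfcomp = s == revcomp_dna(s)
    ct = oligo_nm * 1e-9
    if selfcomp:
        ds += _SYM_DS
        x = 1.0
    else:
        x = 4.0
    ds += 0.368 * (len(s) - 1) * math.log(monovalent_mm / 1000.0)
    return dh * 1000.0 / (ds + R_GAS * math.log(ct / x)) - 273.15


@dataclass(frozen=True)
class PrimerConstraints:
    product_min: int = 100
    product_max: int = 300
    len_min: int = 18
    len_max: int = 25
    tm_min: float = 55.0
    tm_max: float = 62.0
    tm_opt: float = 57.0
    monovalent_mm: float = 50.0
    oligo_nm: float = 50.0


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    fwd_tm: float
    rev_tm: float
    product_size: int
    fwd_start: int      # 0-based on the template
    rev_end: int        # half-open end of the product on the template
    target_locus: SSRLocus

    def rank_key(self, tm_opt: float = 57.0) -> Tuple[float, float]:
        mean = (self.fwd_tm + self.rev_tm) / 2.0
        return (abs(mean - tm_opt), abs(self.fwd_tm - self.rev_tm))


def _tm_windows(seq: str, lo: int, hi: int, c: PrimerConstraints) -> List[Tuple[int, int, float]]:
    """(start, end, Tm) of every constraint-satisfying window in seq[lo:hi]."""
    out = []
    for start in range(lo, hi):
        for length in range(c.len_min, c.len_max + 1):
            end = start + length
            if end > hi:
                break
            tm = melt_tm(seq[start:end], c.monovalent_mm, c.oligo_nm)
            if c.tm_min <= tm <= c.tm_max:
                out.append((start, end, tm))
    return out


def design_primer_pairs(transcript: Transcript, locus: SSRLocus,
                        constraints: PrimerConstraints = PrimerConstraints(),
                        max_pairs: int = 10) -> List[PrimerPair]:
    """Ranked primer pairs flanking ``locus``; empty list (with a logged
    reason) when the flanks admit no constraint-satisfying pair."""
    c = constraints
    s = transcript.seq
    n = len(s)
    if locus.start < c.len_min + 2 or n - locus.end < c.len_min + 2:
        log.info("locus %s:%d-%d: flanks too short for primer design",
                 locus.transcript_id, locus.start, locus.end)
        return []
    # a product must contain the run and stay <= product_max long
    fwd_lo = max(0, locus.end - c.product_max)
    fwds = _tm_windows(s, fwd_lo, locus.start, c)
    rev_hi = min(n, locus.start + c.product_max)
    revs = _tm_windows(s, locus.end, rev_hi, c)
    pairs: List[PrimerPair] = []
    for fs, fe, ftm in fwds:
        if fe > locus.start:
            continue
        for rs, re_, rtm in revs:
            product = re_ - fs
            if product < c.product_min:
                continue
            if product > c.product_max:
                continue
            pairs.append(PrimerPair(
                forward_seq=s[fs:fe],
                reverse_seq=revcomp_dna(s[rs:re_]),
                fwd_tm=ftm, rev_tm=rtm,
                product_size=product,
                fwd_start=fs, rev_end=re_,
                target_locus=locus,
            ))
    if not pairs:
        log.info("locus %s:%d-%d: no primer pair satisfies the constraints",
                 locus.transcript_id, locus.start, locus.end)
        return []
    pairs.sort(key=lambda p: (p.rank_key(c.tm_opt), p.fwd_start, p.rev_end))
    return pairs[:max_pairs]


def amplify(transcript: Transcript, pair: PrimerPair) -> str:
    """In-silico PCR product: the template substring between the primer sites."""
    return transcript.seq[pair.fwd_start:pair.rev_end]
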