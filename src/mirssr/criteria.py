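"""The four precursor acceptance criteria and the AMFE/MFEI statistics.

A candidate hairpin is accepted when, in its MFE structure,

1. the >= 20 nt mature sequence sits entirely within one arm of the hairpin,
2. the window is thermodynamically miRNA-like: MFEI >= threshold (0.70 by
   default; typical mRNA sits near 0.62-0.66, rRNA 0.59, tRNA 0.64),
3. at most six mature bases are unpaired against the star arm
   ("mismatches", bulges included), and
4. the mature neither intersects the terminal loop nor contains an unpaired
   run longer than ``max_internal_gap`` (no loop or break in the mature).

AMFE = |dG| / window length x 100;  MFEI = AMFE / GC%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .fold import FoldResult, gc_percent
from .homology import PrecursorCandidate

Arm = str  # "5p" | "3p" | "none"


@dataclass(frozen=True)
class CriteriaThresholds:
    mfei_threshold: float = 0.70
    max_star_mismatches: int = 6
    max_internal_gap: int = 3
    min_arm_len: int = 20


@dataclass
class HairpinEvaluation:
    candidate: Optional[PrecursorCandidate]
    fold: FoldResult
    arm: Arm
    star_mismatches: int
    loop_break_ok: bool
    gc_pct: float
    amfe: float
    mfei: float
    passes: Dict[str, bool]
    verdict: bool
    fail_reason: str = ""


@dataclass
class MfeiSummary:
    n: int
    mean: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def terminal_loop(fold: FoldResult) -> Optional[Tuple[int, int]]:
    """The terminal loop of the main hairpin, as a 0-based half-open interval.

    Among all hairpin loops (pairs enclosing no other pair), the one whose
    closing pair is enclosed by the largest number of pairs is taken to belong
    to the longest stem; ties break toward the leftmost loop.  Returns None
    for structures without pairs.
    """
    if not fold.pairs:
        return None
    pairs = fold.pairs
    hairpin_closers = [
        (i, j) for (i, j) in pairs
        if not any(i < a and b < j for (a, b) in pairs)
    ]
    def depth(p):
        i, j = p
        return sum(1 for (a, b) in pairs if a <= i and j <= b)
    i, j = max(hairpin_closers, key=lambda p: (depth(p), -p[0]))
    return (i + 1, j)


def assign_arm(fold: FoldResult, mature_span: Tuple[int, int]) -> Arm:
    """Which hairpin arm carries the mature: ``5p``, ``3p`` or ``none``.

    ``5p``/``3p`` require that the mature does not intersect the terminal
    loop and that every paired mature base pairs to a partner on the opposite
    side of that loop; anything else (no pairs at all, loop overlap, a mature
    split across two stems) is ``none``.
    """
    ms, me = mature_span
    if not (0 <= ms < me <= len(fold.seq)):
        raise ValueError("mature span outside folded sequence")
    tl = terminal_loop(fold)
    if tl is None:
        return "none"
    ls, le = tl
    if ms < le and ls < me:  # intersects the terminal loop
        return "none"
    pm = fold.pair_map()
    partners = [pm[k] for k in range(ms, me) if k in pm]
    if me <= ls:
        return "5p" if all(p >= le for p in partners) else "none"
    return "3p" if all(p < ls for p in partners) else "none"


def count_star_mismatches(fold: FoldResult, mature_span: Tuple[int, int]) -> int:
    """Number of mature positions left unpaired in the MFE structure
    (bulged or mismatched against the star arm).

    Usage error if the mature is not assignable to an arm.
    """
    if assign_arm(fold, mature_span) == "none":
        raise ValueError("count_star_mismatches: mature is not on a hairpin arm")
    return _unpaired_in_span(fold, mature_span)


def _unpaired_in_span(fold: FoldResult, span: Tuple[int, int]) -> int:
    pm = fold.pair_map()
    return sum(1 for k in range(*span) if k not in pm)


def check_loop_break(fold: FoldResult, mature_span: Tuple[int, int],
                     max_internal_gap: int = 3) -> bool:
    """True iff the mature avoids the terminal loop and contains no run of
    more than ``max_internal_gap`` consecutive unpaired bases."""
    ms, me = mature_span
    tl = terminal_loop(fold)
    if tl is not None:
        ls, le = tl
        if ms < le and ls < me:
            return False
    pm = fold.pair_map()
    run = 0
    for k in range(ms, me):
        if k in pm:
            run = 0
        else:
            run += 1
            if run > max_internal_gap:
                return False
    return True


def compute_mfei(delta_g_mag: float, length: int, gc_pct: float) -> Tuple[float, float]:
    """(AMFE, MFEI) from a |dG| magnitude, a window length and a GC%."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_pct <= 100:
        raise ValueError("gc_pct must be in (0, 100]")
    amfe = delta_g_mag / length * 100.0
    return amfe, amfe / gc_pct


def evaluate_candidate(candidate: PrecursorCandidate, fold: FoldResult,
                       thresholds: CriteriaThresholds = CriteriaThresholds()
                       ) -> HairpinEvaluation:
    """Apply criteria 1-4 to one folded precursor window."""
    if fold.seq != candidate.seq:
        raise ValueError("fold does not correspond to candidate sequence")
    span = candidate.mature_span
    arm = assign_arm(fold, span)
    star = _unpaired_in_span(fold, span)
    loop_ok = check_loop_break(fold, span, thresholds.max_internal_gap)
    gc = gc_percent(fold.seq)
    reason = ""
    if gc == 0.0:
        amfe, mfei = 0.0, 0.0
        mfei_ok = False
        reason = "GC content is zero; MFEI undefined"
    else:
        amfe, mfei = compute_mfei(fold.delta_g_mag, len(fold.seq), gc)
        mfei_ok = mfei >= thresholds.mfei_threshold
    passes = {
        "arm": arm != "none" and candidate.mature_len >= thresholds.min_arm_len,
        "mfei": mfei_ok,
        "star_mismatch": star <= thresholds.max_star_mismatches,
        "loop_break": loop_ok,
    }
    verdict = all(passes.values())
    if not verdict and not reason:
        reason = ",".join(k for k, v in passes.items() if not v)
    return HairpinEvaluation(
        candidate=candidate, fold=fold, arm=arm, star_mismatches=star,
        loop_break_ok=loop_ok, gc_pct=gc, amfe=amfe, mfei=mfei,
        passes=passes, verdict=verdict, fail_reason=reason,
    )


def summarize_mfei(evals: Union[Sequence[HairpinEvaluation], Sequence[float]]
                   ) -> MfeiSummary:
    """n / mean / min / max of MFEI values; the mean is reported to two
    decimals with round-half-up.  Accepts evaluations or raw MFEI values."""
    values: List[float] = []
    for e in evals:
        values.append(e.mfei if isinstance(e, HairpinEvaluation) else float(e))
    if not values:
        return MfeiSummary(n=0)
    return MfeiSummary(
        n=len(values),
        mean=_round_half_up(sum(values) / len(values)),
        min=_round_half_up(min(values)),
        max=_round_half_up(max(values)),
    )
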