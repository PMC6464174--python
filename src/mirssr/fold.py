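"""Pseudoknot-free minimum-free-energy folding of short RNAs.

Two energy models are provided:

``pair_count``
    The classic base-pair-maximization model (Nussinov-style): every allowed
    pair scores 1 and the reported ``delta_g_mag`` is the pair count times a
    1.0 kcal/mol surrogate.  This model is simple enough to cross-check by
    exhaustive enumeration (:func:`enumerate_structures`) and is used by the
    test oracles.

``stacking``
    A nearest-neighbor helix-stacking model: free energy is the sum of the
    published RNA stack terms for every pair that sits directly on another
    pair.  Hairpin/internal/bulge loops carry no penalty and there are no
    dangling ends, so this is deliberately *not* the full Turner model — it is
    the smallest model that yields kcal/mol-scaled ΔG magnitudes adequate for
    hairpin-arm geometry and MFEI decisions.

Both models allow Watson-Crick and G·U wobble pairs and enforce a minimum
hairpin loop of 3 unpaired nucleotides for *every* pair.  Folding is a
standard O(n^3) dynamic program, vectorized per diagonal, with a fully
deterministic traceback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

#: allowed base pairs (Watson-Crick + wobble)
PAIR_RULES = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                        ("G", "U"), ("U", "G")})

# Nearest-neighbor stack free energies, kcal/mol at 37 degC, for an outer pair
# (i, j) stacked on an inner pair (i+1, j-1).  The ten canonical Watson-Crick
# values are the standard published RNA set; the remaining combinations follow
# from rotational symmetry: dG(outer, inner) == dG(reversed inner, reversed outer).
_WC_STACKS: Dict[Tuple[Tuple[str, str], Tuple[str, str]], float] = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("A", "U")): -2.11,
    (("C", "G"), ("U", "A")): -2.08,
    (("G", "C"), ("A", "U")): -2.35,
    (("G", "C"), ("U", "A")): -2.24,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}
# Wobble-containing stacks: single representative values (one wobble pair in
# the stack, or both).  Kept coarse on purpose; see the methods note.
_GU_SINGLE = -1.2
_GU_DOUBLE = -0.5


def stack_energy(outer: Tuple[str, str], inner: Tuple[str, str]) -> float:
    """Free energy (kcal/mol, negative = stabilizing) of ``outer`` on ``inner``."""
    if outer not in PAIR_RULES or inner not in PAIR_RULES:
        raise ValueError(f"not an allowed pair: {outer} / {inner}")
    key = (outer, inner)
    if key in _WC_STACKS:
        return _WC_STACKS[key]
    rot = ((inner[1], inner[0]), (outer[1], outer[0]))
    if rot in _WC_STACKS:
        return _WC_STACKS[rot]
    n_wobble = sum(1 for p in (outer, inner) if "G" in p and "U" in p)
    return _GU_DOUBLE if n_wobble == 2 else _GU_SINGLE


@dataclass(frozen=True)
class EnergyModel:
    """Folding model: ``pair_count`` or ``stacking`` (see module docstring)."""

    name: str
    min_loop: int = 3

    def __post_init__(self):
        if self.name not in ("pair_count", "stacking"):
            raise ValueError(f"unknown energy model {self.name!r}")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")


PAIR_COUNT = EnergyModel("pair_count")
STACKING = EnergyModel("stacking")

MAX_FOLD_LEN = 2000
MAX_ENUM_LEN = 14


@dataclass
class FoldResult:
    """MFE structure of one sequence.

    ``delta_g_mag`` is the magnitude of the (negative) free energy, i.e. a
    non-negative stability score: the pair count under ``pair_count`` and
    kcal/mol under ``stacking``.
    """

    seq: str
    dotbracket: str
    pairs: List[Tuple[int, int]]
    delta_g_mag: float
    model: EnergyModel = field(default=STACKING, repr=False)

    def pair_map(self) -> Dict[int, int]:
        m: Dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


def _validate_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - RNA_ALPHABET - {"N"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def pairs_to_dotbracket(n: int, pairs: List[Tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> List[Tuple[int, int]]:
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), k))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def gc_percent(seq: str) -> float:
    """GC content as a percentage on [0, 100]; empty input is an error."""
    if not seq:
        raise ValueError("gc_percent of empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def _pair_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    chars = np.array(list(seq))
    ok = np.zeros((n, n), dtype=bool)
    for a, b in PAIR_RULES:
        ok |= (chars[:, None] == a) & (chars[None, :] == b)
    return ok


def _stack_matrix(seq: str, pairable: np.ndarray) -> np.ndarray:
    """S[i, j] = score (positive) of stacking pair (i,j) on pair (i+1,j-1)."""
    n = len(seq)
    S = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j - 1 > i + 1 and pairable[i, j] and pairable[i + 1, j - 1]:
                S[i, j] = -stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
    return S


def _dp(seq: str, model: EnergyModel):
    """Fill W/V score matrices (maximized stability score, >= 0)."""
    n = len(seq)
    minl = model.min_loop
    P = _pair_matrix(seq)
    S = _stack_matrix(seq, P) if model.name == "stacking" else None
    NEG = -1e18
    # padded to (n+1, n+1): row n stays 0 so W[k+1, j] with k == j reads 0
    W = np.zeros((n + 1, n + 1))
    V = np.full((n + 1, n + 1), NEG)
    for d in range(minl + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        pair_ok = P[i, j]
        if model.name == "pair_count":
            vd = 1.0 + W[i + 1, j - 1]
        else:
            vd = W[i + 1, j - 1].copy()
            if d - 3 >= minl:
                inner_ok = P[i + 1, j - 1]
                stacked = S[i, j] + V[i + 1, j - 1]
                vd = np.where(inner_ok, np.maximum(vd, stacked), vd)
        V[i, j] = np.where(pair_ok, vd, NEG)
        best = W[i + 1, j].copy()
        for t in range(minl + 1, d + 1):
            k = i + t
            cand = V[i, k] + W[k + 1, j]
            np.maximum(best, cand, out=best)
        W[i, j] = best
    return W, V, P, S


def _traceback(seq: str, model: EnergyModel, W, V, P, S) -> List[Tuple[int, int]]:
    n = len(seq)
    minl = model.min_loop
    pairs: List[Tuple[int, int]] = []
    agenda: List[Tuple[str, int, int]] = [("W", 0, n - 1)]
    close = lambda a, b: math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9)
    while agenda:
        tag, i, j = agenda.pop()
        if i >= j:
            continue
        if tag == "W":
            w = W[i, j]
            if close(w, 0.0) or close(w, W[i + 1, j]):
                # leave i unpaired unless pairing strictly improves the score
                agenda.append(("W", i + 1, j))
                continue
            for k in range(i + minl + 1, j + 1):
                if P[i, k] and close(V[i, k] + W[k + 1, j], w):
                    agenda.append(("V", i, k))
                    agenda.append(("W", k + 1, j))
                    break
            else:  # numerical safety net; should not happen
                agenda.append(("W", i + 1, j))
        else:  # V: (i, j) is paired
            pairs.append((i, j))
            if model.name == "stacking":
                stackable = (j - 1 - (i + 1) - 1 >= minl and P[i + 1, j - 1])
                if stackable and close(V[i, j], S[i, j] + V[i + 1, j - 1]):
                    agenda.append(("V", i + 1, j - 1))
                else:
                    agenda.append(("W", i + 1, j - 1))
            else:
                agenda.append(("W", i + 1, j - 1))
    return sorted(pairs)


def fold_mfe(seq: str, model: EnergyModel = STACKING) -> FoldResult:
    """Fold ``seq`` (RNA or DNA letters) to its model-optimal structure.

    The traceback is deterministic: a base is paired only when pairing
    strictly improves the score, with the smallest admissible partner, and
    helix continuation is preferred between equal-score branches.
    """
    seq = _validate_rna(seq)
    if len(seq) > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    n = len(seq)
    if n <= model.min_loop + 1:
        return FoldResult(seq, "." * n, [], 0.0, model)
    W, V, P, S = _dp(seq, model)
    score = float(W[0, n - 1])
    pairs = _traceback(seq, model, W, V, P, S)
    return FoldResult(seq, pairs_to_dotbracket(n, pairs), pairs, score, model)


def score_structure(seq: str, pairs: FrozenSet[Tuple[int, int]],
                    model: EnergyModel = PAIR_COUNT) -> float:
    """Score an explicit structure under ``model`` (used by the oracle)."""
    if model.name == "pair_count":
        return float(len(pairs))
    pset = set(pairs)
    total = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pset:
            total += -stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))
    return total


def _all_structures(seq: str, i: int, j: int, P, minl: int, memo):
    """All nested, constraint-respecting pair sets on seq[i..j] (inclusive)."""
    if i >= j:
        return [frozenset()]
    key = (i, j)
    if key in memo:
        return memo[key]
    out = [s for s in _all_structures(seq, i + 1, j, P, minl, memo)]
    for k in range(i + minl + 1, j + 1):
        if P[i, k]:
            for left in _all_structures(seq, i + 1, k - 1, P, minl, memo):
                for right in _all_structures(seq, k + 1, j, P, minl, memo):
                    out.append(left | right | {(i, k)})
    memo[key] = out
    return out


def enumerate_structures(seq: str, model: EnergyModel = PAIR_COUNT) -> float:
    """Exhaustively enumerate all structures and return the best score.

    Testing oracle only: refuses sequences longer than 14 nt (combinatorial
    explosion guard).
    """
    seq = _validate_rna(seq)
    if len(seq) > MAX_ENUM_LEN:
        raise ValueError(f"enumeration limited to {MAX_ENUM_LEN} nt")
    P = _pair_matrix(seq)
    memo: dict = {}
    structures = _all_structures(seq, 0, len(seq) - 1, P, model.min_loop, memo)
    return max(score_structure(seq, s, model) for s in structures)


def write_ct(fold: FoldResult, path: str, title: str = "mirssr") -> None:
    """Write the structure as a connectivity table (CT) for external viewers."""
    pm = fold.pair_map()
    n = len(fold.seq)
    with open(path, "w") as fh:
        fh.write(f"{n}\tdG = -{fold.delta_g_mag:.2f}\t{title}\n")
        for k in range(n):
            partner = pm.get(k, -1) + 1
            fh.write(f"{k + 1}\t{fold.seq[k]}\t{k}\t{k + 2 if k + 1 < n else 0}"
                     f"\t{partner}\t{k + 1}\n")
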