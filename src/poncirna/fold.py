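"""Nested RNA secondary-structure prediction with a simplified energy model.

The engine finds the minimum-free-energy *nested* structure (no pseudoknots)
under a deliberately small thermodynamic model:

* a base pair stacked directly on another pair contributes a stacking energy
  that depends on its own identity: G-C/C-G -3.0, A-U/U-A -2.0,
  G-U/U-G -1.0 kcal/mol;
* every hairpin loop costs +3.0 kcal/mol to close;
* hairpin loops contain at least 3 unpaired bases;
* all other loops (bulges, interior loops, multiloops) are free.

The model is not meant to reproduce Turner-parameter folders such as RNAfold
or Mfold; absolute energies from those programs are treated as data, never
recomputed here. What the simplified model preserves is the *geometry* a
hairpin-based miRNA validator needs: perfect-complement stems fold back, and
longer/stronger stems score lower. Any external folder can be substituted by
providing the same (sequence -> HairpinStructure) contract.

The O(n^3) dynamic program is JIT-compiled with numba; the traceback runs in
plain Python over the filled matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import encode, is_valid

HAIRPIN_CLOSURE = 3.0
MIN_LOOP = 3
MAX_FOLD_LEN = 2000

_INF = 1e9
_EPS = 1e-9

# _STACK[a, b]: contribution of pair (a, b) when stacked on the enclosing
# pair; 0 where (a, b) cannot pair. Codes: A=0, C=1, G=2, T/U=3.
_STACK = np.zeros((4, 4), dtype=np.float64)
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b, _e in [(0, 3, -2.0), (3, 0, -2.0), (2, 1, -3.0), (1, 2, -3.0),
                   (2, 3, -1.0), (3, 2, -1.0)]:
    _STACK[_a, _b] = _e
    _PAIRABLE[_a, _b] = True


@dataclass
class HairpinStructure:
    """A folded sequence: dot-bracket string, energy, and explicit pair set."""

    sequence: str
    pairing: str
    mfe: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def partner(self) -> list[int | None]:
        """Per-position pairing partner (None where unpaired)."""
        p: list[int | None] = [None] * len(self.sequence)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p


@njit(cache=True)
def _fill(seq, pairable, stack, min_loop, hairpin_cost):  # pragma: no cover
    n = seq.shape[0]
    V = np.full((n, n), _INF)
    W = np.zeros((n, n))
    Wp = np.full((n, n), _INF)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # V: minimum energy of [i, j] given (i, j) paired
            if pairable[seq[i], seq[j]]:
                best = hairpin_cost
                if j - i - 1 > min_loop + 1 and pairable[seq[i + 1], seq[j - 1]]:
                    s = V[i + 1, j - 1] + stack[seq[i + 1], seq[j - 1]]
                    if s < best:
                        best = s
                if Wp[i + 1, j - 1] < best:  # interior / multibranch, no bonus
                    best = Wp[i + 1, j - 1]
                V[i, j] = best
            # W (any structure incl. empty) and Wp (>= 1 pair) over [i, j]
            w = W[i, j - 1]
            wp = Wp[i, j - 1]
            for k in range(i, j - min_loop):
                if V[k, j] < _INF / 2:
                    left = W[i, k - 1] if k > i else 0.0
                    cand = V[k, j] + left
                    if cand < wp:
                        wp = cand
            if wp < w:
                w = wp
            W[i, j] = w
            Wp[i, j] = wp
    return V, W, Wp


def _traceback(seq: np.ndarray, V, W, Wp) -> list[tuple[int, int]]:
    """Recover one optimal structure from the filled matrices."""
    pairs: list[tuple[int, int]] = []
    jobs = [("W", 0, len(seq) - 1)]
    while jobs:
        kind, i, j = jobs.pop()
        if j - i <= MIN_LOOP:
            continue
        if kind == "V":
            pairs.append((i, j))
            v = V[i, j]
            if (
                j - i - 1 > MIN_LOOP + 1
                and _PAIRABLE[seq[i + 1], seq[j - 1]]
                and abs(V[i + 1, j - 1] + _STACK[seq[i + 1], seq[j - 1]] - v) < _EPS
            ):
                jobs.append(("V", i + 1, j - 1))
            elif Wp[i + 1, j - 1] < _INF / 2 and abs(Wp[i + 1, j - 1] - v) < _EPS:
                jobs.append(("Wp", i + 1, j - 1))
            # otherwise (i, j) closes a hairpin: nothing inside
            continue
        target = W[i, j] if kind == "W" else Wp[i, j]
        if kind == "W" and target >= -_EPS:
            continue  # empty structure is optimal for this region
        if target > _INF / 2:
            continue
        prev = W[i, j - 1] if kind == "W" else Wp[i, j - 1]
        if abs(target - prev) < _EPS:
            jobs.append((kind, i, j - 1))
            continue
        placed = False
        for k in range(i, j - MIN_LOOP):
            if V[k, j] > _INF / 2:
                continue
            left = W[i, k - 1] if k > i else 0.0
            if abs(V[k, j] + left - target) < _EPS:
                jobs.append(("V", k, j))
                if k > i:
                    jobs.append(("W", i, k - 1))
                placed = True
                break
        if not placed:  # pragma: no cover - defensive
            raise RuntimeError("fold traceback failed")
    return pairs


def fold(sequence: str) -> HairpinStructure:
    """Fold a sequence into its minimum-energy nested structure.

    Parameters
    ----------
    sequence : str
        RNA or DNA spelling (T and U are equivalent). Ambiguous bases are
        rejected.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if len(sequence) > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if not is_valid(sequence):
        raise ValueError("sequence contains non-ACGTU characters")
    seq = encode(sequence)
    n = len(seq)
    if n <= MIN_LOOP + 1:
        return HairpinStructure(sequence, "." * n, 0.0, [])
    V, W, Wp = _fill(seq, _PAIRABLE, _STACK, MIN_LOOP, HAIRPIN_CLOSURE)
    mfe = float(min(0.0, W[0, n - 1]))
    pairs = _traceback(seq, V, W, Wp) if mfe < -_EPS else []
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return HairpinStructure(sequence, "".join(db), mfe, sorted(pairs))


def structure_energy(sequence: str, pairs) -> float:
    """Energy of an explicit nested structure under the built-in model.

    Each pair stacked directly inside another pair contributes its stacking
    energy; each hairpin loop (a pair enclosing no other pair) costs +3.0.
    """
    seq = encode(sequence)
    pair_set = {tuple(p) for p in pairs}
    e = 0.0
    for i, j in pair_set:
        if (i - 1, j + 1) in pair_set:
            e += _STACK[seq[i], seq[j]]
        if not any(i < a and b < j for a, b in pair_set):
            e += HAIRPIN_CLOSURE
    return e
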