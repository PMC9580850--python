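"""Minimum-free-energy secondary-structure prediction (simplified model).

The masking and amplicon filters need a deterministic folding engine
that answers two questions: how stable is the most stable pseudoknot-
free structure of a sequence (delta G, kcal/mol), and which positions
are paired in it.  The model implemented here is deliberately simple
enough to be verified exhaustively:

* pairs: Watson-Crick (A:T, C:G) plus the G:T wobble; N never pairs;
  every pair (i, j) must enclose at least 3 unpaired-capable bases
  (j - i >= 4);
* a helix is a run of consecutively stacked pairs; its energy is the
  sum of stack terms from a fixed built-in table; helices shorter than
  3 pairs contribute nothing (they are treated as unpaired);
* a helix whose innermost pair encloses no other contributing helix
  closes a hairpin loop and pays a positive length penalty
  ``3.0 + 0.3 * (loop - 3)`` kcal/mol;
* bulges, internal loops and multiloops carry no penalty.

delta G is the minimum of this energy over all pseudoknot-free
structures (0 for the empty structure), found by an interval dynamic
program.  The ``temperature`` argument is part of the engine contract;
the built-in table is parameterized at the qPCR annealing temperature
(60 C) and is not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq import encode

__all__ = ["StructureResult", "BuiltinFolder", "fold", "PAIR_TYPE", "STACK", "hairpin_penalty"]

MIN_HELIX = 3
MIN_LOOP = 3
HAIRPIN_BASE = 3.0
HAIRPIN_PER_NT = 0.3
_INF = 1e18

# pair-type ids over codes (A=0, C=1, G=2, T=3, N=4): AT=0 TA=1 CG=2 GC=3 GT=4 TG=5
PAIR_TYPE = np.full((5, 5), -1, dtype=np.int8)
PAIR_TYPE[0, 3] = 0  # A:T
PAIR_TYPE[3, 0] = 1  # T:A
PAIR_TYPE[1, 2] = 2  # C:G
PAIR_TYPE[2, 1] = 3  # G:C
PAIR_TYPE[2, 3] = 4  # G:T wobble
PAIR_TYPE[3, 2] = 5  # T:G wobble

# stack energy (kcal/mol) between an outer and the adjacent inner pair,
# derived from per-pair strengths (WC G:C 3, WC A:T 2, wobble 1)
_STRENGTH = np.array([2.0, 2.0, 3.0, 3.0, 1.0, 1.0])
STACK = 0.4 - 0.5 * (_STRENGTH[:, None] + _STRENGTH[None, :])
STACK.setflags(write=False)


def hairpin_penalty(loop_len: int) -> float:
    """Destabilizing free energy of a hairpin loop of *loop_len* nt (>= 3)."""
    return HAIRPIN_BASE + HAIRPIN_PER_NT * (loop_len - MIN_LOOP)


@dataclass(frozen=True)
class StructureResult:
    """MFE fold: delta_g (<= 0, 0 means unstructured) and the pairing."""

    delta_g: float
    pairing: str
    pairs: tuple[tuple[int, int], ...]

    @property
    def paired_positions(self) -> frozenset:
        out = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return frozenset(out)


@njit(cache=True)
def _fold_kernel(code, pairtype, stack, hp_a, hp_b, min_helix):  # pragma: no cover
    n = code.shape[0]
    run = np.zeros((n, n), np.int64)
    H = np.full((n, n), _INF)
    BP = np.full((n, n), _INF)
    B = np.zeros((n, n))
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            pt = pairtype[code[i], code[j]]
            if pt >= 0:
                inner = 0
                if (j - 1) - (i + 1) >= 4 and pairtype[code[i + 1], code[j - 1]] >= 0:
                    inner = run[i + 1, j - 1]
                r = 1 + inner
                run[i, j] = r
                if r >= min_helix:
                    stacksum = 0.0
                    for L in range(2, r + 1):
                        p_out = pairtype[code[i + L - 2], code[j - L + 2]]
                        p_in = pairtype[code[i + L - 1], code[j - L + 1]]
                        stacksum += stack[p_out, p_in]
                        if L >= min_helix:
                            a = i + L
                            b = j - L
                            loop_len = j - i - 2 * L + 1
                            interior = hp_a + hp_b * (loop_len - 3)
                            if a <= b and BP[a, b] < interior:
                                interior = BP[a, b]
                            cand = stacksum + interior
                            if cand < H[i, j]:
                                H[i, j] = cand
            best_bp = _INF
            if j - 1 - i >= 4:
                best_bp = BP[i, j - 1]
            for k in range(i, j - 3):
                if H[k, j] < _INF:
                    left = 0.0
                    if k > i:
                        left = B[i, k - 1]
                    v = left + H[k, j]
                    if v < best_bp:
                        best_bp = v
            BP[i, j] = best_bp
            if best_bp < 0.0:
                B[i, j] = best_bp
    return run, H, BP, B


_EPS = 1e-7


def _trace_helix(k, j, code, run, H, BP, stack, pairtype, pairs):
    r = run[k, j]
    stacksum = 0.0
    for L in range(2, r + 1):
        p_out = pairtype[code[k + L - 2], code[j - L + 2]]
        p_in = pairtype[code[k + L - 1], code[j - L + 1]]
        stacksum += stack[p_out, p_in]
        if L >= MIN_HELIX:
            a, b = k + L, j - L
            loop_len = j - k - 2 * L + 1
            g = hairpin_penalty(loop_len)
            interior = g
            has_inner = a <= b and BP[a, b] < _INF / 2
            if has_inner and BP[a, b] < interior:
                interior = BP[a, b]
            if abs(stacksum + interior - H[k, j]) <= _EPS:
                for d in range(L):
                    pairs.append((k + d, j - d))
                if has_inner and BP[a, b] < g - _EPS:
                    _trace_bp(a, b, code, run, H, BP, stack, pairtype, pairs)
                return
    raise AssertionError("traceback failed inside helix")


def _trace_bp(i, j, code, run, H, BP, stack, pairtype, pairs):
    while True:
        if j - 1 - i >= 4 and BP[i, j - 1] <= BP[i, j] + _EPS:
            j -= 1
            continue
        for k in range(i, j - 3):
            if H[k, j] >= _INF / 2:
                continue
            left = B_VAL(BP, i, k)  # min(0, BP[i, k-1]) with k == i -> 0
            if abs(left + H[k, j] - BP[i, j]) <= _EPS:
                _trace_helix(k, j, code, run, H, BP, stack, pairtype, pairs)
                if k > i and BP[i, k - 1] < -_EPS:
                    _trace_bp(i, k - 1, code, run, H, BP, stack, pairtype, pairs)
                return
        raise AssertionError("traceback failed at interval")


def B_VAL(BP, i, k):
    if k == i:
        return 0.0
    v = BP[i, k - 1]
    return v if v < 0.0 else 0.0


def fold(sequence: str, temperature: float = 60.0) -> StructureResult:
    """Return the minimum-free-energy structure of *sequence*.

    Deterministic for a fixed input (ties broken by a fixed traceback
    order).  Raises on an empty sequence.
    """
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    seq = sequence.upper()
    code = encode(seq)
    if np.any(code > 4):
        raise ValueError("sequence contains invalid bases")
    n = len(seq)
    if n < MIN_LOOP + 2:
        return StructureResult(0.0, "." * n, ())
    run, H, BP, B = _fold_kernel(
        code, PAIR_TYPE, STACK, HAIRPIN_BASE, HAIRPIN_PER_NT, MIN_HELIX
    )
    dg = float(B[0, n - 1])
    if dg >= 0.0:
        return StructureResult(0.0, "." * n, ())
    pairs: list[tuple[int, int]] = []
    _trace_bp(0, n - 1, code, run, H, BP, STACK, PAIR_TYPE, pairs)
    pairs.sort()
    dots = ["."] * n
    for i, j in pairs:
        dots[i] = "("
        dots[j] = ")"
    return StructureResult(dg, "".join(dots), tuple(pairs))


class BuiltinFolder:
    """The built-in folding engine (callable engine contract)."""

    def fold(self, sequence: str, temperature: float = 60.0) -> StructureResult:
        return fold(sequence, temperature)

    def __call__(self, sequence: str, temperature: float = 60.0) -> StructureResult:
        return fold(sequence, temperature)
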