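"""Dynamic-programming kernel for single-hairpin RNA folding.

The energy model is a deliberately simple, fully documented approximation
(not Turner rules): canonical (A:U, G:C) and wobble (G:U) pairs; helix
stacking bonuses that depend only on the two pair types; a hairpin-loop
initiation penalty plus a per-nucleotide charge for loops beyond 3 nt; and a
per-nucleotide charge for interior/bulge nucleotides between consecutive
pairs, capped at ``MAX_INTERIOR`` unpaired nucleotides per interior loop.
All constants are binary fractions so energy comparisons are exact in
floating point.

Structures are restricted to single-hairpin topologies: the pair set forms a
chain (i1<i2<...<ik<jk<...<j1) with exactly one terminal loop of >= 3 nt.
The kernel fills, for every candidate outermost pair (i, j):

* ``E[i, j]`` — minimum energy of a chain rooted at pair (i, j);
* ``C[i, j]`` — maximum number of pairs among minimum-energy chains
  (the documented tie-break prefers more pairs, then the lexicographically
  smallest pair list).

Plain-Python loops, jit-compiled with numba when available; results are
identical either way.
"""

from __future__ import annotations

import numpy as np

MAX_INTERIOR = 12  # max unpaired nt between consecutive pairs (a + b)
HAIRPIN_INIT = 4.0
HAIRPIN_PER_NT = 0.5  # per unpaired loop nt beyond 3
INTERIOR_PER_NT = 1.0
MIN_LOOP = 3
_INF = 1e30

# base codes: A=0 C=1 G=2 U=3; pair types: GC=0 AU=1 GU=2, -1 = not pairable
PAIR_TYPE = np.full((4, 4), -1, dtype=np.int8)
PAIR_TYPE[2, 1] = PAIR_TYPE[1, 2] = 0
PAIR_TYPE[0, 3] = PAIR_TYPE[3, 0] = 1
PAIR_TYPE[2, 3] = PAIR_TYPE[3, 2] = 2

# stack bonus indexed by (outer pair type, inner pair type)
STACK = np.array(
    [
        [-2.0, -1.5, -0.5],
        [-1.5, -1.0, -0.5],
        [-0.5, -0.5, -0.5],
    ]
)

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int8)


def hairpin_energy(loop_len: int) -> float:
    return HAIRPIN_INIT + HAIRPIN_PER_NT * max(0, loop_len - MIN_LOOP)


def _fill_tables(codes, E, C):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = PAIR_TYPE[codes[i], codes[j]]
            if pt < 0:
                continue
            loop = span - 1
            best = HAIRPIN_INIT + HAIRPIN_PER_NT * (loop - MIN_LOOP)
            best_c = 1
            for a in range(0, MAX_INTERIOR + 1):
                ii = i + 1 + a
                for b in range(0, MAX_INTERIOR + 1 - a):
                    jj = j - 1 - b
                    if jj - ii < MIN_LOOP + 1:
                        break
                    e_in = E[ii, jj]
                    if e_in >= _INF:
                        continue
                    if a == 0 and b == 0:
                        cost = STACK[pt, PAIR_TYPE[codes[ii], codes[jj]]]
                    else:
                        cost = INTERIOR_PER_NT * (a + b)
                    tot = e_in + cost
                    cnt = C[ii, jj] + 1
                    if tot < best or (tot == best and cnt > best_c):
                        best = tot
                        best_c = cnt
            E[i, j] = best
            C[i, j] = best_c


try:  # optional jit; identical semantics without it
    from numba import njit

    _fill_tables = njit(cache=True)(_fill_tables)
except ImportError:  # pragma: no cover
    pass


def fold(seq_codes: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Return (pairs, mfe) for the best single-hairpin chain.

    ``pairs`` are 0-based (i, j) tuples ordered outermost-first; empty with
    mfe 0.0 when no admissible structure has energy <= 0.
    """
    n = int(seq_codes.shape[0])
    E = np.full((n, n), _INF)
    C = np.zeros((n, n), dtype=np.int32)
    if n > MIN_LOOP + 1:
        _fill_tables(seq_codes, E, C)

    best_key = (0.0, 0)  # empty structure: energy 0, zero pairs
    best_ij = None
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if E[i, j] < _INF:
                key = (float(E[i, j]), -int(C[i, j]))
                if key < best_key:
                    best_key = key
                    best_ij = (i, j)
    if best_ij is None:
        return [], 0.0

    mfe = best_key[0]
    pairs: list[tuple[int, int]] = []
    i, j = best_ij
    while True:
        pairs.append((i, j))
        if C[i, j] == 1:  # terminal: closes the hairpin loop
            break
        found = False
        for a in range(0, MAX_INTERIOR + 1):
            ii = i + 1 + a
            # b descending => inner j ascending => lexicographically smallest
            for b in range(min(MAX_INTERIOR - a, j - ii - MIN_LOOP - 2), -1, -1):
                jj = j - 1 - b
                if jj - ii < MIN_LOOP + 1 or jj >= j:
                    continue
                if E[ii, jj] >= _INF:
                    continue
                if a == 0 and b == 0:
                    cost = float(STACK[PAIR_TYPE[seq_codes[i], seq_codes[j]],
                                       PAIR_TYPE[seq_codes[ii], seq_codes[jj]]])
                else:
                    cost = INTERIOR_PER_NT * (a + b)
                if E[ii, jj] + cost == E[i, j] and C[ii, jj] + 1 == C[i, j]:
                    i, j = ii, jj
                    found = True
                    break
            if found:
                break
        if not found:  # inconsistent tables; cannot happen
            raise AssertionError("fold traceback failed")
    return pairs, mfe
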