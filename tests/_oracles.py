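"""Independent brute-force oracles used by the test suite.

These recompute results by exhaustive enumeration under the same documented
model constants as the implementation, but share none of its code paths:
folding enumerates every single-hairpin chain recursively; duplex scoring
enumerates every monotone alignment path within the gap budget.
"""

from __future__ import annotations

from boronmir._fold import (
    HAIRPIN_INIT,
    HAIRPIN_PER_NT,
    INTERIOR_PER_NT,
    MAX_INTERIOR,
    MIN_LOOP,
    PAIR_TYPE,
    STACK,
    encode,
)

# --- folding ---------------------------------------------------------------


def _chain_energy(chain, codes) -> float:
    e = 0.0
    for k in range(len(chain) - 1):
        (i, j), (ii, jj) = chain[k], chain[k + 1]
        a, b = ii - i - 1, j - jj - 1
        if a == 0 and b == 0:
            e += STACK[PAIR_TYPE[codes[i], codes[j]], PAIR_TYPE[codes[ii], codes[jj]]]
        else:
            e += INTERIOR_PER_NT * (a + b)
    i, j = chain[-1]
    e += HAIRPIN_INIT + HAIRPIN_PER_NT * max(0, (j - i - 1) - MIN_LOOP)
    return e


def _all_chains(codes):
    n = len(codes)

    def extend(i, j):
        yield [(i, j)]
        for ii in range(i + 1, j):
            for jj in range(j - 1, ii + MIN_LOOP, -1):
                a, b = ii - i - 1, j - jj - 1
                if a + b > MAX_INTERIOR:
                    continue
                if PAIR_TYPE[codes[ii], codes[jj]] < 0:
                    continue
                for rest in extend(ii, jj):
                    yield [(i, j)] + rest

    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if PAIR_TYPE[codes[i], codes[j]] >= 0:
                yield from extend(i, j)


def best_fold_bruteforce(seq: str):
    """(pairs, mfe) of the best chain by exhaustive enumeration.

    Selection key mirrors the documented tie-break: lowest energy, then most
    pairs, then lexicographically smallest pair list; the empty structure
    (energy 0) participates.
    """
    codes = encode(seq)
    best = (0.0, 0, [])
    for chain in _all_chains(codes):
        key = (_chain_energy(chain, codes), -len(chain), chain)
        if key < best:
            best = key
    return best[2], best[0]


# --- duplex scoring --------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC = {(0, 3), (3, 0), (2, 1), (1, 2)}
_WOBBLE = {(2, 3), (3, 2)}


def _w(mpos: int) -> float:
    return 2.0 if 2 <= mpos <= 13 else 1.0


def best_duplex_bruteforce(mirna: str, window: str, max_gaps: int = 3) -> float:
    """Minimum duplex penalty by enumerating every alignment path."""
    m = [_CODE[b] for b in mirna]
    t = [_CODE[b] for b in reversed(window)]
    L, W = len(m), len(t)
    best = [float("inf")]

    def walk(i: int, j: int, gaps: int, pen: float) -> None:
        if pen >= best[0]:
            return
        if i == L and j == W:
            best[0] = pen
            return
        if i < L and j < W:
            pair = (m[i], t[j])
            if pair in _WC:
                c = 0.0
            elif pair in _WOBBLE:
                c = 0.5 * _w(i + 1)
            else:
                c = 1.0 * _w(i + 1)
            walk(i + 1, j + 1, gaps, pen + c)
        if gaps < max_gaps:
            if i < L:
                walk(i + 1, j, gaps + 1, pen + 2.0 * _w(i + 1))
            if j < W:
                walk(i, j + 1, gaps + 1, pen + 2.0 * _w(min(i + 1, L)))

    walk(0, 0, 0, 0.0)
    return best[0]
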