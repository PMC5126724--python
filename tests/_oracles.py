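"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's seeded/chained detection path and
its edlib-backed aligner: the repeat oracle enumerates every anti-diagonal
of the circular sequence exhaustively, and the alignment oracle is a plain
unit-cost edit-distance DP.
"""

import numpy as np

_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _CODE[ord(_b)] = _i
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip("ACGT", "TGCA"):
    _COMP[ord(_a)] = _CODE[ord(_b)]
_COMP_SHIFT = np.where(_COMP > 0, _COMP, np.uint8(255))


def brute_force_max_inverted_pair(seq: str, min_len: int) -> int:
    """Length of the longest disjoint inverted-repeat pair (0 if none).

    Exhaustive: for every anti-diagonal constant c the per-base match array
    ``seq[a] == complement(seq[c - a])`` is scanned for maximal circular
    runs.  A run equal to its own image (a palindromic stretch) contributes
    its half length.  Pairs whose removal leaves fewer than two non-empty
    single-copy segments are discarded, mirroring the structural definition.
    """
    n = len(seq)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    fwd = _CODE[raw]
    comp = _COMP_SHIFT[raw]
    idx = np.arange(n)
    best = 0
    for c in range(n):
        match = fwd == comp[(c - idx) % n]
        if not match.any():
            continue
        if match.all():
            best = max(best, n // 2 if n // 2 >= min_len else 0)
            continue
        f0 = int(np.argmin(match))
        rolled = np.roll(match, -f0)
        d = np.diff(rolled.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if rolled[-1]:
            ends = np.append(ends, n)
        for s, e in zip(starts, ends):
            a0, length = int(s + f0) % n, int(e - s)
            if length < min_len:
                continue
            b0 = (c - (a0 + length - 1)) % n
            if b0 == a0:  # palindromic: split into halves
                half = length // 2
                gap_inside = length - 2 * half
                if half < min_len or gap_inside == 0:
                    continue
                a_iv, b_iv = (a0, half), ((a0 + length - half) % n, half)
                length = half
            else:
                a_iv, b_iv = (a0, length), (b0, length)
            gap1 = (b_iv[0] - (a_iv[0] + a_iv[1])) % n
            gap2 = (a_iv[0] - (b_iv[0] + b_iv[1])) % n
            if gap1 == 0 or gap2 == 0:
                continue
            best = max(best, length)
    return best


def edit_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance by full DP."""
    na, nb = len(a), len(b)
    prev = np.arange(nb + 1)
    barr = np.frombuffer(b.encode(), dtype="S1")
    for i in range(1, na + 1):
        cur = np.empty(nb + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (barr != a[i - 1].encode())
        cur[1:] = np.minimum(sub, prev[1:] + 1)
        np.minimum.accumulate(cur - np.arange(nb + 1), out=cur)
        cur += np.arange(nb + 1)
        prev = cur
    return int(prev[-1])
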