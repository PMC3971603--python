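"""Independent alignment oracles for cross-checking the package.

These are deliberately separate implementations: plain dynamic-programming
matrix fills (numba-accelerated) with a Python traceback, sharing no code
with the package's alignment paths.  All identities are
matches / alignment columns * 100.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000.0

_ENC = {c: i for i, c in enumerate("ACGT")}


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in seq], dtype=np.int8)


@njit(cache=True)
def _nw_fill(a, b, match, mism, gap):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        H[i, 0] = i * gap
    for j in range(1, m + 1):
        H[0, j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mism
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    return H


def nw_identity(a: str, b: str, match=1.0, mism=-1.0, gap=-2.0):
    """(score, identity%) of an optimal global alignment, all columns counted."""
    ea, eb = encode(a), encode(b)
    H = _nw_fill(ea, eb, match, mism, gap)
    i, j = len(ea), len(eb)
    matches = columns = 0
    while i > 0 or j > 0:
        s = match if (i > 0 and j > 0 and ea[i - 1] == eb[j - 1]) else mism
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + s):
            matches += int(ea[i - 1] == eb[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] + gap):
            i -= 1
        else:
            j -= 1
        columns += 1
    return H[len(ea), len(eb)], 100.0 * matches / columns


@njit(cache=True)
def _sw_fill(a, b, match, mism, gap):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mism
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
    return H


def sw_identity(a: str, b: str, match=1.0, mism=-1.0, gap=-2.0):
    """(score, identity%, ref_start, ref_end) of the optimal local alignment."""
    ea, eb = encode(a), encode(b)
    H = _sw_fill(ea, eb, match, mism, gap)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    score = H[i, j]
    ref_end = int(i)
    matches = columns = 0
    while H[i, j] > 0:
        s = match if (i > 0 and j > 0 and ea[i - 1] == eb[j - 1]) else mism
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + s):
            matches += int(ea[i - 1] == eb[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] + gap):
            i -= 1
        else:
            j -= 1
        columns += 1
    if columns == 0:
        return score, 0.0, 0, 0
    return score, 100.0 * matches / columns, int(i), ref_end


@njit(cache=True)
def _semiglobal_fill(a, b, match, mism, go, ge):
    """Affine-gap semi-global: b end-to-end, free gaps at a's ends.

    Returns (M, X, Y): M ends in an aligned pair, X in a gap in b (a char
    skipped), Y in a gap in a (b char skipped).  Alignment may start at any
    position of a for free and end at any position of a for free.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    for i in range(n + 1):
        M[i, 0] = 0.0  # free leading flank of a
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mism
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge)
    return M, X, Y


def semiglobal_identity(ref: str, read: str, match=1.0, mism=-1.0,
                        go=-2.0, ge=-1.0):
    """(score, identity%, columns) of the optimal semi-global alignment."""
    a, b = encode(ref), encode(read)
    n, m = len(a), len(b)
    M, X, Y = _semiglobal_fill(a, b, match, mism, go, ge)
    ends = np.maximum(np.maximum(M[:, m], X[:, m]), Y[:, m])
    i = int(np.argmax(ends))
    score = ends[i]
    # determine which matrix attains the end
    if np.isclose(M[i, m], score):
        state = "M"
    elif np.isclose(X[i, m], score):
        state = "X"
    else:
        state = "Y"
    j = m
    matches = columns = 0
    while j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mism
            matches += int(a[i - 1] == b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if j == 0:
                columns += 1
                break
            if np.isclose(M[i, j], target):
                state = "M"
            elif np.isclose(X[i, j], target):
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if np.isclose(X[i, j], M[i - 1, j] + go):
                state = "M"
            i -= 1
        else:
            if np.isclose(Y[i, j], M[i, j - 1] + go):
                state = "M"
            j -= 1
        columns += 1
    if columns == 0:
        return score, 0.0, 0
    return score, 100.0 * matches / columns, columns


def brute_force_overlap(a: str, b: str, min_len: int, min_ident: float = 0.0):
    """Best qualifying ungapped overlap of b against a (one strand).

    Plain character loops over every offset; returns (offset, length,
    identity) of the score-maximising (length x identity) overlap meeting
    both thresholds, or None.
    """
    best = None
    for off in range(-len(b) + 1, len(a)):
        start = max(0, off)
        end = min(len(a), off + len(b))
        length = end - start
        if length < min_len:
            continue
        matches = sum(1 for p in range(start, end) if a[p] == b[p - off])
        ident = 100.0 * matches / length
        if ident < min_ident:
            continue
        score = length * ident
        if best is None or score > best[0]:
            best = (score, off, length, ident)
    if best is None:
        return None
    return best[1], best[2], best[3]


def brute_force_primer_prefix(seq: str, primer: str, max_mismatch: int,
                              slack: int, iupac: dict[str, str]):
    """Bases to cut from the 5' end by scanning every offset exhaustively."""
    best = None
    for off in range(slack + 1):
        if off + len(primer) > len(seq):
            continue
        window = seq[off:off + len(primer)]
        mm = sum(1 for p, c in zip(primer, window) if c not in iupac.get(p, p))
        if mm <= max_mismatch:
            key = (mm, -(off + len(primer)))
            if best is None or key < best[0]:
                best = (key, off + len(primer))
    return best[1] if best else 0
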