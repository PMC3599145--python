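"""Numba kernels for global pairwise alignment and all-pairs distances.

Scoring: match +1, mismatch -1, gap -2, terminal gaps free. Ambiguity codes
(anything encoded >= 4) never match, not even themselves. The distance is
(mismatched columns + internal gap columns) / (columns excluding
terminal-gap columns).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# A C G T get codes 0-3; every other IUPAC symbol a distinct code >= 4 so it
# mismatches everything including itself.
_ALPHABET = "ACGTNRYSWKMBDHV"
ENCODE = {c: i for i, c in enumerate(_ALPHABET)}


def encode(residues: str) -> np.ndarray:
    return np.frombuffer(
        bytes(ENCODE[c] for c in residues), dtype=np.uint8
    ).copy()


@njit(cache=False)
def nw_counts(a, b):  # pragma: no cover - exercised via wrappers
    """Needleman-Wunsch with free terminal gaps.

    Returns (mismatch_columns, internal_gap_columns, scored_columns, score).
    Traceback tie-break: diagonal > up > left, from the bottom-right corner.
    """
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            sub = 1 if (ai == bj and ai < 4) else -1
            best = S[i - 1, j - 1] + sub
            up = S[i - 1, j] + (-2 if j < m else 0)
            if up > best:
                best = up
            left = S[i, j - 1] + (-2 if i < n else 0)
            if left > best:
                best = left
            S[i, j] = best
    i, j = n, m
    mism = 0
    igap = 0
    cols = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            ai = a[i - 1]
            bj = b[j - 1]
            sub = 1 if (ai == bj and ai < 4) else -1
            if S[i, j] == S[i - 1, j - 1] + sub:
                if sub < 0:
                    mism += 1
                cols += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and S[i, j] == S[i - 1, j] + (0 if (j == 0 or j == m) else -2):
            # gap in b; terminal iff b has not started or is exhausted
            if 0 < j < m:
                igap += 1
                cols += 1
            i -= 1
            continue
        if 0 < i < n:
            igap += 1
            cols += 1
        j -= 1
    return mism, igap, cols, S[n, m]


@njit(cache=False)
def _dist_from_counts(mism, igap, cols):
    if cols == 0:
        return 0.0
    return (mism + igap) / cols


@njit(cache=False)
def nw_distance(a, b):
    mism, igap, cols, _ = nw_counts(a, b)
    return _dist_from_counts(mism, igap, cols)


@njit(cache=False)
def all_pairs_seq(seqs, lens, order):
    """Distances for all unordered pairs of encoded, padded sequences.

    `order` gives, per sequence, the rank of its residue string in a fixed
    canonical (lexicographic) ordering; the pair is always aligned with the
    canonically smaller sequence as the first argument so that the traceback
    tie-break cannot break d(a,b) == d(b,a).
    Returns a flat array in (i, j), i<j row-major pair order.
    """
    n = seqs.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if order[i] <= order[j]:
                out[k] = nw_distance(seqs[i, : lens[i]], seqs[j, : lens[j]])
            else:
                out[k] = nw_distance(seqs[j, : lens[j]], seqs[i, : lens[i]])
            k += 1
    return out
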