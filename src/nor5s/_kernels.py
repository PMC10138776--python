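"""Numba dynamic-programming kernels for pairwise alignment.

Scores are affine-gap (Gotoh): a gap of length L costs ``-(open + (L-1)*ext)``
with ``open``/``ext`` passed as negative numbers, i.e. ``open`` is charged on
the first gapped column and ``ext`` on each further column.

The kernels fill and return the full score matrices; traceback happens in
:mod:`nor5s.align` by replaying the recurrences with a fixed tie-break order,
which keeps the hot loops branch-light.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(2**30))


@njit(cache=True)
def fill_local(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap in b (up)
    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_ext
            e2 = H[i, j - 1] + gap_open
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] + gap_ext
            f2 = H[i - 1, j] + gap_open
            if f2 > f:
                f = f2
            F[i, j] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h
            if h > best:
                best = h
                best_i = i
                best_j = j
    return best, best_i, best_j, H, E, F


@njit(cache=True)
def fill_global(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    H = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_ext
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_ext
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_ext
            e2 = H[i, j - 1] + gap_open
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] + gap_ext
            f2 = H[i - 1, j] + gap_open
            if f2 > f:
                f = f2
            F[i, j] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h
    return H, E, F
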