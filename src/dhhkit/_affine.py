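"""Affine-gap global alignment core shared by pairwise and profile alignment.

The dynamic program maximizes over three states per cell (match, gap-up,
gap-left).  The first residue of a gap run costs ``gap_open`` and each further
residue ``gap_extend``, so a run of length L costs ``gap_open + (L-1) *
gap_extend``.  Traceback ties are broken deterministically in the order
diagonal > up > left.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def affine_align(M, gap_open, gap_extend):  # pragma: no cover - jit kernel
    """Align two "sequences" given their pair score matrix ``M`` (n x m).

    Returns ``(score, ops)`` where ``ops`` is an int8 array over the path from
    the start, with 0 = diagonal (consume one of each), 1 = up (gap in the
    second sequence), 2 = left (gap in the first sequence).
    """
    n, m = M.shape
    S = np.full((3, n + 1, m + 1), NEG_INF)
    P = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    S[0, 0, 0] = 0.0
    for i in range(1, n + 1):
        S[1, i, 0] = -(gap_open + (i - 1) * gap_extend)
        P[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        S[2, 0, j] = -(gap_open + (j - 1) * gap_extend)
        P[2, 0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: predecessors at (i-1, j-1); tie order 0 > 1 > 2
            best = S[0, i - 1, j - 1]
            arg = 0
            if S[1, i - 1, j - 1] > best:
                best = S[1, i - 1, j - 1]
                arg = 1
            if S[2, i - 1, j - 1] > best:
                best = S[2, i - 1, j - 1]
                arg = 2
            S[0, i, j] = best + M[i - 1, j - 1]
            P[0, i, j] = arg

            # up state (gap in second sequence): predecessors at (i-1, j)
            best = S[0, i - 1, j] - gap_open
            arg = 0
            if S[1, i - 1, j] - gap_extend > best:
                best = S[1, i - 1, j] - gap_extend
                arg = 1
            if S[2, i - 1, j] - gap_open > best:
                best = S[2, i - 1, j] - gap_open
                arg = 2
            S[1, i, j] = best
            P[1, i, j] = arg

            # left state (gap in first sequence): predecessors at (i, j-1)
            best = S[0, i, j - 1] - gap_open
            arg = 0
            if S[1, i, j - 1] - gap_open > best:
                best = S[1, i, j - 1] - gap_open
                arg = 1
            if S[2, i, j - 1] - gap_extend > best:
                best = S[2, i, j - 1] - gap_extend
                arg = 2
            S[2, i, j] = best
            P[2, i, j] = arg

    state = 0
    score = S[0, n, m]
    if S[1, n, m] > score:
        score = S[1, n, m]
        state = 1
    if S[2, n, m] > score:
        score = S[2, n, m]
        state = 2

    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        ops[k] = state
        prev = P[state, i, j]
        if state == 0:
            i -= 1
            j -= 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = prev
    return score, ops[k:]
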