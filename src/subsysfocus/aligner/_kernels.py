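"""Numba kernels: affine-gap local alignment with an optional diagonal band.

The full (unbanded) path doubles as the exhaustive Smith-Waterman oracle
used for truth construction; the banded path is the seeded heuristic's
extension stage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**6)

# result vector layout
R_SCORE, R_QS, R_QE, R_SS, R_SE, R_MATCH, R_MISM, R_GAPOPEN, R_ALNLEN = range(9)


@njit(cache=True)
def sw_align(q, s, submat, gap_open, gap_extend, dlo, dhi):  # pragma: no cover
    """Local alignment of q vs s restricted to diagonals j-i in [dlo, dhi].

    Returns int64[9]: raw score, 0-based inclusive q/s start/end, match,
    mismatch and gap-opening counts, and alignment length in columns.
    A first gap residue costs gap_open + gap_extend.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in q (left moves)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in s (up moves)
    # pointers: 0 stop, 1 diag, 2 up (gap in s), 3 left (gap in q)
    PH = np.zeros((m + 1, n + 1), dtype=np.int8)
    PE = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 if E opened here
    PF = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + submat[q[i - 1], s[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    res = np.zeros(9, dtype=np.int64)
    res[R_SCORE] = best
    if best <= 0:
        return res
    # traceback
    i = bi
    j = bj
    matches = 0
    mismatches = 0
    gapopens = 0
    alnlen = 0
    state = 0  # 0 in H, 2 in F, 3 in E
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                alnlen += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            alnlen += 1
            opened = PF[i, j]
            i -= 1
            if opened == 1:
                gapopens += 1
                state = 0
        else:
            alnlen += 1
            opened = PE[i, j]
            j -= 1
            if opened == 1:
                gapopens += 1
                state = 0
    res[R_QS] = i
    res[R_QE] = bi - 1
    res[R_SS] = j
    res[R_SE] = bj - 1
    res[R_MATCH] = matches
    res[R_MISM] = mismatches
    res[R_GAPOPEN] = gapopens
    res[R_ALNLEN] = alnlen
    return res
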