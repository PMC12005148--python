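"""Numba-jitted Gotoh local alignment kernel shared by the protein-vs-codon
and nucleotide aligners.

Affine gaps: a gap of length L costs ``gap_open + gap_extend * L``.
Tie-breaks are fixed so the whole pipeline is deterministic: the best cell is
the *first* maximum in row-major order (smallest query end, then target end)
and the traceback prefers diagonal over query-gap over target-gap moves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -(10**9)


@njit(cache=False)
def sw_affine(q, t, S, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    ptrE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended, 0 = opened
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    Frow = np.full(m + 1, _NEG, np.int64)
    best = 0
    bi = 0
    bj = 0
    go = gap_open
    ge = gap_extend
    for i in range(1, n + 1):
        E = _NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            e1 = H[i, j - 1] - go - ge
            e2 = E - ge
            if e2 > e1:
                E = e2
                ptrE[i, j] = 1
            else:
                E = e1
                ptrE[i, j] = 0
            f1 = H[i - 1, j] - go - ge
            f2 = Frow[j] - ge
            if f2 > f1:
                F = f2
                ptrF[i, j] = 1
            else:
                F = f1
                ptrF[i, j] = 0
            Frow[j] = F
            d = H[i - 1, j - 1] + S[qi, t[j - 1]]
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E > h:
                h = E
                p = 2
            if F > h:
                h = F
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


def traceback(ptrH, ptrE, ptrF, bi, bj):
    """Walk pointers back from the best cell.

    Returns ``(columns, q_start, t_start)`` where columns is a list of
    ``(state, q_index, t_index)`` with state in {diag, qgap, tgap}; ``qgap``
    consumes target only, ``tgap`` consumes query only.
    """
    cols = []
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                cols.append(("diag", i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            pe = ptrE[i, j]
            cols.append(("qgap", -1, j - 1))
            j -= 1
            if pe == 0:
                state = 0
        else:
            pf = ptrF[i, j]
            cols.append(("tgap", i - 1, -1))
            i -= 1
            if pf == 0:
                state = 0
    cols.reverse()
    return cols, i, j
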