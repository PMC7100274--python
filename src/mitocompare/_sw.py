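"""Smith-Waterman kernels (numba-compiled).

One banded affine-gap local aligner serves both the exact small-input path
(band covering the whole matrix) and the seed-anchored genome-scale path
(narrow band around a seed chain's diagonal range).

Cost model: a gap of length L costs gap_open + gap_extend * L (the opening
charge is paid once, every gap column pays the extension charge).

Alignment column ops: 0 '=' match, 1 'X' mismatch, 2 'I' gap in the first
sequence (consumes b), 3 'D' gap in the second sequence (consumes a).
"""

from __future__ import annotations

import numpy as np
from numba import njit

OP_EQ, OP_X, OP_I, OP_D = 0, 1, 2, 3

_NEG = -(10**15)


@njit(cache=True)
def sw_banded(a, b, d_lo, d_hi, match, mismatch, gap_open, gap_extend):
    """Banded local alignment of uint8-coded sequences a, b.

    Cells (i, j) with d_lo <= j - i <= d_hi are inside the band
    (i over a, j over b, both 1-based in DP space). Returns
    (score, a_start, a_end, b_start, b_end, ops) with 0-based half-open
    coordinates; ops is an int8 array of per-column operations.
    """
    n = a.shape[0]
    m = b.shape[0]
    W = d_hi - d_lo + 1

    H_prev = np.full(W, _NEG, np.int64)
    F_prev = np.full(W, _NEG, np.int64)
    H_cur = np.full(W, _NEG, np.int64)
    F_cur = np.full(W, _NEG, np.int64)

    ptrH = np.zeros((n + 1, W), np.uint8)
    ptrE = np.zeros((n + 1, W), np.uint8)
    ptrF = np.zeros((n + 1, W), np.uint8)

    best = 0
    best_i = 0
    best_c = 0

    # row 0
    for c in range(W):
        j = c + d_lo
        if 0 <= j <= m:
            H_prev[c] = 0
        else:
            H_prev[c] = _NEG
        F_prev[c] = _NEG

    for i in range(1, n + 1):
        E = _NEG
        for c in range(W):
            j = c + i + d_lo
            if j < 0 or j > m:
                H_cur[c] = _NEG
                F_cur[c] = _NEG
                if j < 0:
                    E = _NEG
                continue
            if j == 0:
                H_cur[c] = 0
                F_cur[c] = _NEG
                E = _NEG
                ptrH[i, c] = 0
                continue
            # E: gap in a (consume b), depends on (i, j-1) = band col c-1
            if c >= 1 and H_cur[c - 1] > _NEG // 2:
                e_open = H_cur[c - 1] + gap_open + gap_extend
            else:
                e_open = _NEG
            e_ext = E + gap_extend if E > _NEG // 2 else _NEG
            if e_open >= e_ext:
                E = e_open
                ptrE[i, c] = 0
            else:
                E = e_ext
                ptrE[i, c] = 1
            # F: gap in b (consume a), depends on (i-1, j) = band col c+1
            if c + 1 < W and H_prev[c + 1] > _NEG // 2:
                f_open = H_prev[c + 1] + gap_open + gap_extend
            else:
                f_open = _NEG
            if c + 1 < W and F_prev[c + 1] > _NEG // 2:
                f_ext = F_prev[c + 1] + gap_extend
            else:
                f_ext = _NEG
            if f_open >= f_ext:
                F_cur[c] = f_open
                ptrF[i, c] = 0
            else:
                F_cur[c] = f_ext
                ptrF[i, c] = 1
            # H
            if H_prev[c] > _NEG // 2:
                ai = a[i - 1]
                bj = b[j - 1]
                if ai == bj and ai < 4:
                    diag = H_prev[c] + match
                else:
                    diag = H_prev[c] + mismatch
            else:
                diag = _NEG
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E > h:
                h = E
                p = 2
            if F_cur[c] > h:
                h = F_cur[c]
                p = 3
            H_cur[c] = h
            ptrH[i, c] = p
            if h > best:
                best = h
                best_i = i
                best_c = c
        # swap rows
        for c in range(W):
            H_prev[c] = H_cur[c]
            F_prev[c] = F_cur[c]
            H_cur[c] = _NEG
            F_cur[c] = _NEG

    # traceback
    ops = np.empty(n + m, np.int8)
    nops = 0
    i = best_i
    c = best_c
    j = c + i + d_lo
    a_end = i
    b_end = j
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, c]
            if p == 0:
                break
            if p == 1:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    ops[nops] = OP_EQ
                else:
                    ops[nops] = OP_X
                nops += 1
                i -= 1
                j -= 1
                # c unchanged
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = OP_I
            nops += 1
            if ptrE[i, c] == 0:
                state = 0
            j -= 1
            c -= 1
        else:
            ops[nops] = OP_D
            nops += 1
            if ptrF[i, c] == 0:
                state = 0
            i -= 1
            c += 1
    out = ops[:nops][::-1].copy()
    return best, i, a_end, j, b_end, out
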