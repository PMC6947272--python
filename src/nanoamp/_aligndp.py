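"""Numba kernel for ends-free affine-gap pairwise alignment.

Glocal dynamic programming: leading and trailing *read* overhangs cost a
small linear per-base penalty (reads carry barcode remnants and ragged
ends, which stay cheap to leave unaligned), while the reference is paid for
end to end — unaligned reference ends cost deletion gaps.  Together these
keep large-insertion paths from being silently traded for clipping.
Gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Tie-breaking is
deterministic: match/mismatch preferred over deletion (gap in read)
preferred over insertion (gap in ref) at equal score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10 ** 8))

# op codes emitted by the traceback
OP_MATCH = 0
OP_MISMATCH = 1
OP_INS = 2  # read base not in ref (gap in reference)
OP_DEL = 3  # ref base not in read (gap in read)


@njit(cache=True, nogil=True)
def align_full(ref, read, match, mismatch, gap_open, gap_extend, overhang):
    """Full alignment with traceback.  See module docstring for conventions.

    Pointers are packed per cell into one uint8:
    bits 0-1 = H choice (0 M, 1 Y/del, 2 X/ins); bit 2 = Y extended;
    bit 3 = X extended.
    """
    m = ref.shape[0]
    n = read.shape[0]

    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)

    h_prev = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        h_prev[j] = overhang * j  # leading read overhang, linear cost
    h_curr = np.zeros(n + 1, dtype=np.int32)
    y_prev = np.full(n + 1, NEG_INF, dtype=np.int32)
    y_curr = np.full(n + 1, NEG_INF, dtype=np.int32)

    best_score = np.int32(0)
    bi = 0
    bj = 0

    for i in range(1, m + 1):
        # column 0: the whole reference prefix is a (paid) deletion
        y_curr[0] = gap_open + (i - 1) * gap_extend
        h_curr[0] = y_curr[0]
        x = NEG_INF
        ri = ref[i - 1]
        prow = ptr[i]
        for j in range(1, n + 1):
            if ri == read[j - 1]:
                sm = h_prev[j - 1] + match
            else:
                sm = h_prev[j - 1] + mismatch

            yo = h_prev[j] + gap_open
            ye = y_prev[j] + gap_extend
            if yo >= ye:
                y = yo
                pt = np.uint8(0)
            else:
                y = ye
                pt = np.uint8(4)
            y_curr[j] = y

            xo = h_curr[j - 1] + gap_open
            xe = x + gap_extend
            if xo >= xe:
                x = xo
            else:
                x = xe
                pt |= np.uint8(8)

            best = sm
            if y > best:
                best = y
                pt |= np.uint8(1)
            if x > best:
                best = x
                pt = (pt & np.uint8(12)) | np.uint8(2)
            h_curr[j] = best
            prow[j] = pt

        tmp = h_prev
        h_prev = h_curr
        h_curr = tmp
        tmp = y_prev
        y_prev = y_curr
        y_curr = tmp

    # h_prev holds row m.  The reference must be exhausted; the read suffix
    # overhang costs `overhang` per base.
    best_score = NEG_INF
    bi = m
    bj = 0
    for j in range(n + 1):
        sc = h_prev[j] + overhang * (n - j)
        if sc > best_score:
            best_score = sc
            bj = j

    # Traceback from (bi, bj) until a free boundary is reached.
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i = bi
    j = bj
    state = ptr[i, j] & np.uint8(3)
    while i > 0 and j > 0:
        if state == 0:
            k -= 1
            if ref[i - 1] == read[j - 1]:
                ops[k] = OP_MATCH
            else:
                ops[k] = OP_MISMATCH
            i -= 1
            j -= 1
            state = ptr[i, j] & np.uint8(3)
        elif state == 1:
            k -= 1
            ops[k] = OP_DEL
            extended = ptr[i, j] & np.uint8(4)
            i -= 1
            if extended:
                state = np.uint8(1)
            else:
                state = ptr[i, j] & np.uint8(3)
        else:
            k -= 1
            ops[k] = OP_INS
            extended = ptr[i, j] & np.uint8(8)
            j -= 1
            if extended:
                state = np.uint8(2)
            else:
                state = ptr[i, j] & np.uint8(3)

    return best_score, i, j, bi, bj, ops[k:]
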