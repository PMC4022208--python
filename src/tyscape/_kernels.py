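"""Numba dynamic-programming kernels backing the alignment engine.

All kernels operate on uint8 code arrays (A=0, C=1, G=2, T=3; 4 = unmatchable,
i.e. N or soft-masked input).  Code 4 always scores as a mismatch and the
columns it occupies are excluded from identity bookkeeping.

Gap model: a gap of length L costs gap_open + L * gap_extend.
"""

import numba as nb
import numpy as np

NEG = -1_000_000_000


@nb.njit(cache=True)
def sw_full(a, b, match, mismatch, gap_open, gap_extend):
    """Full Smith-Waterman with affine gaps and traceback.

    Returns (score, a0, a1, b0, b1, matches, columns, n_columns) where the
    intervals are 0-based half-open and n_columns counts aligned columns
    involving an unmatchable symbol.
    """
    n = a.shape[0]
    m = b.shape[0]
    tb = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    te = np.zeros((n + 1, m + 1), np.uint8)  # 1 = gap extension
    tf = np.zeros((n + 1, m + 1), np.uint8)
    h_prev = np.zeros(m + 1, np.int32)
    h_cur = np.zeros(m + 1, np.int32)
    f_row = np.full(m + 1, NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        e = NEG
        h_cur[0] = 0
        ca = a[i - 1]
        for j in range(1, m + 1):
            # E: gap in a (consume b[j-1]); from (i, j-1)
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_ext > e_open:
                e = e_ext
                te[i, j] = 1
            else:
                e = e_open
            # F: gap in b (consume a[i-1]); from (i-1, j)
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_row[j] - gap_extend
            if f_ext > f_open:
                f_row[j] = f_ext
                tf[i, j] = 1
            else:
                f_row[j] = f_open
            cb = b[j - 1]
            if ca >= 4 or cb >= 4 or ca != cb:
                s = mismatch
            else:
                s = match
            d = h_prev[j - 1] + s
            h = 0
            t = 0
            if d > h:
                h = d
                t = 1
            if e > h:
                h = e
                t = 2
            if f_row[j] > h:
                h = f_row[j]
                t = 3
            h_cur[j] = h
            tb[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    # traceback
    matches = 0
    cols = 0
    ncols = 0
    i = bi
    j = bj
    state = 0  # 0 H, 1 E, 2 F
    while True:
        if state == 0:
            t = tb[i, j]
            if t == 0:
                break
            if t == 1:
                ca = a[i - 1]
                cb = b[j - 1]
                cols += 1
                if ca >= 4 or cb >= 4:
                    ncols += 1
                elif ca == cb:
                    matches += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if b[j - 1] >= 4:
                ncols += 1
            ext = te[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            if a[i - 1] >= 4:
                ncols += 1
            ext = tf[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, matches, cols, ncols


@nb.njit(cache=True)
def sw_banded(a, b, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded Smith-Waterman restricted to diagonals d = j - i in [dlo, dhi].

    Same return convention as sw_full.  Cells outside the band are
    unreachable for gap moves; fresh local starts (H = 0) are allowed
    anywhere inside the band.
    """
    n = a.shape[0]
    m = b.shape[0]
    w_band = dhi - dlo + 1
    H = np.zeros((n + 1, w_band), np.int32)
    E = np.full((n + 1, w_band), NEG, np.int32)
    F = np.full((n + 1, w_band), NEG, np.int32)
    tb = np.zeros((n + 1, w_band), np.uint8)
    te = np.zeros((n + 1, w_band), np.uint8)
    tf = np.zeros((n + 1, w_band), np.uint8)
    best = 0
    bi = 0
    bw = 0
    for i in range(1, n + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > m:
            jhi = m
        ca = a[i - 1]
        for j in range(jlo, jhi + 1):
            w = j - i - dlo
            e = NEG
            eflag = np.uint8(0)
            if w - 1 >= 0:
                e_open = H[i, w - 1] - gap_open - gap_extend
                e_ext = E[i, w - 1] - gap_extend
                if e_ext > e_open:
                    e = e_ext
                    eflag = np.uint8(1)
                else:
                    e = e_open
            E[i, w] = e
            te[i, w] = eflag
            f = NEG
            fflag = np.uint8(0)
            if w + 1 < w_band:
                f_open = H[i - 1, w + 1] - gap_open - gap_extend
                f_ext = F[i - 1, w + 1] - gap_extend
                if f_ext > f_open:
                    f = f_ext
                    fflag = np.uint8(1)
                else:
                    f = f_open
            F[i, w] = f
            tf[i, w] = fflag
            cb = b[j - 1]
            if ca >= 4 or cb >= 4 or ca != cb:
                s = mismatch
            else:
                s = match
            # diagonal predecessor (i-1, j-1) shares the same band offset w
            d = H[i - 1, w] + s
            h = 0
            t = np.uint8(0)
            if d > h:
                h = d
                t = np.uint8(1)
            if e > h:
                h = e
                t = np.uint8(2)
            if f > h:
                h = f
                t = np.uint8(3)
            H[i, w] = h
            tb[i, w] = t
            if h > best:
                best = h
                bi = i
                bw = w
    matches = 0
    cols = 0
    ncols = 0
    i = bi
    w = bw
    bj = bi + dlo + bw
    state = 0
    while True:
        j = i + dlo + w
        if state == 0:
            t = tb[i, w]
            if t == 0:
                break
            if t == 1:
                ca = a[i - 1]
                cb = b[j - 1]
                cols += 1
                if ca >= 4 or cb >= 4:
                    ncols += 1
                elif ca == cb:
                    matches += 1
                i -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if b[j - 1] >= 4:
                ncols += 1
            ext = te[i, w]
            w -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            if a[i - 1] >= 4:
                ncols += 1
            ext = tf[i, w]
            i -= 1
            w += 1
            if ext == 0:
                state = 0
    return best, i, bi, i + dlo + w, bj, matches, cols, ncols


@nb.njit(cache=True)
def nw_full(a, b, match, mismatch, gap_open, gap_extend):
    """Global (Needleman-Wunsch) affine alignment.

    Returns (score, matches, columns, n_columns); end gaps are penalized.
    """
    n = a.shape[0]
    m = b.shape[0]
    tb = np.zeros((n + 1, m + 1), np.uint8)  # 1 diag, 2 from E, 3 from F
    te = np.zeros((n + 1, m + 1), np.uint8)
    tf = np.zeros((n + 1, m + 1), np.uint8)
    h_prev = np.empty(m + 1, np.int32)
    h_cur = np.empty(m + 1, np.int32)
    f_row = np.full(m + 1, NEG, np.int32)
    h_prev[0] = 0
    for j in range(1, m + 1):
        h_prev[j] = -gap_open - gap_extend * j
        tb[0, j] = 2
        te[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        h_cur[0] = -gap_open - gap_extend * i
        tb[i, 0] = 3
        tf[i, 0] = 1 if i > 1 else 0
        e = NEG
        ca = a[i - 1]
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_ext > e_open:
                e = e_ext
                te[i, j] = 1
            else:
                e = e_open
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_row[j] - gap_extend
            if f_ext > f_open:
                f_row[j] = f_ext
                tf[i, j] = 1
            else:
                f_row[j] = f_open
            cb = b[j - 1]
            if ca >= 4 or cb >= 4 or ca != cb:
                s = mismatch
            else:
                s = match
            d = h_prev[j - 1] + s
            h = d
            t = np.uint8(1)
            if e > h:
                h = e
                t = np.uint8(2)
            if f_row[j] > h:
                h = f_row[j]
                t = np.uint8(3)
            h_cur[j] = h
            tb[i, j] = t
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    score = h_prev[m]
    matches = 0
    cols = 0
    ncols = 0
    i = n
    j = m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            t = tb[i, j]
            if t == 1:
                ca = a[i - 1]
                cb = b[j - 1]
                cols += 1
                if ca >= 4 or cb >= 4:
                    ncols += 1
                elif ca == cb:
                    matches += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if b[j - 1] >= 4:
                ncols += 1
            ext = te[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            if a[i - 1] >= 4:
                ncols += 1
            ext = tf[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return score, matches, cols, ncols


@nb.njit(cache=True)
def nw_profile(S, gap_open, gap_extend):
    """Global affine alignment over a precomputed column-score matrix S.

    Used for profile-profile steps of the progressive aligner.  Returns an
    ops array (0 = diag, 1 = gap in rows/consume column of profile 2,
    2 = gap in columns/consume row of profile 1), ordered 5' to 3'.
    """
    n = S.shape[0]
    m = S.shape[1]
    neg = -1e18
    tb = np.zeros((n + 1, m + 1), np.uint8)
    te = np.zeros((n + 1, m + 1), np.uint8)
    tf = np.zeros((n + 1, m + 1), np.uint8)
    h_prev = np.empty(m + 1, np.float64)
    h_cur = np.empty(m + 1, np.float64)
    f_row = np.full(m + 1, neg, np.float64)
    h_prev[0] = 0.0
    for j in range(1, m + 1):
        h_prev[j] = -gap_open - gap_extend * j
        tb[0, j] = 2
        te[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        h_cur[0] = -gap_open - gap_extend * i
        tb[i, 0] = 3
        tf[i, 0] = 1 if i > 1 else 0
        e = neg
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] - gap_open - gap_extend
            e_ext = e - gap_extend
            if e_ext > e_open:
                e = e_ext
                te[i, j] = 1
            else:
                e = e_open
            f_open = h_prev[j] - gap_open - gap_extend
            f_ext = f_row[j] - gap_extend
            if f_ext > f_open:
                f_row[j] = f_ext
                tf[i, j] = 1
            else:
                f_row[j] = f_open
            d = h_prev[j - 1] + S[i - 1, j - 1]
            h = d
            t = np.uint8(1)
            if e > h:
                h = e
                t = np.uint8(2)
            if f_row[j] > h:
                h = f_row[j]
                t = np.uint8(3)
            h_cur[j] = h
            tb[i, j] = t
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    ops = np.empty(n + m, np.uint8)
    k = 0
    i = n
    j = m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            t = tb[i, j]
            if t == 1:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            ext = te[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            ops[k] = 2
            k += 1
            ext = tf[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return ops[:k][::-1].copy()


@nb.njit(cache=True)
def ungapped_extend(a, b, qpos, spos, k, match, mismatch, xdrop):
    """X-drop ungapped extension of an exact k-mer seed; returns best score."""
    score = k * match
    best = score
    i = qpos + k
    j = spos + k
    while i < a.shape[0] and j < b.shape[0]:
        ca = a[i]
        cb = b[j]
        if ca < 4 and ca == cb:
            score += match
        else:
            score += mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i += 1
        j += 1
    score = best
    i = qpos - 1
    j = spos - 1
    while i >= 0 and j >= 0:
        ca = a[i]
        cb = b[j]
        if ca < 4 and ca == cb:
            score += match
        else:
            score += mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    return best
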