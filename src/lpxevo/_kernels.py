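"""Numba inner loops for alignment and HMM scoring.

Kept free of Python objects: all kernels take plain numpy arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e300


@njit(cache=True)
def sw_fill(a, b, sub, gop, gext):
    """Smith-Waterman affine-gap fill.  A gap of length L costs gop + L*gext.

    Returns (H, E, F) matrices of shape (len(a)+1, len(b)+1); H[i, j] is the
    best local alignment score ending at a[i-1], b[j-1].
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gop - gext
            if E[i, j - 1] - gext > e:
                e = E[i, j - 1] - gext
            E[i, j] = e
            f = H[i - 1, j] - gop - gext
            if F[i - 1, j] - gext > f:
                f = F[i - 1, j] - gext
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def sw_score(a, b, sub, gop, gext):
    """Score-only Smith-Waterman (two rolling rows); returns the optimum."""
    n, m = len(a), len(b)
    Hp = np.zeros(m + 1)
    Fp = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        Hc = np.zeros(m + 1)
        Ec = np.full(m + 1, NEG)
        Fc = np.full(m + 1, NEG)
        for j in range(1, m + 1):
            e = Hc[j - 1] - gop - gext
            if Ec[j - 1] - gext > e:
                e = Ec[j - 1] - gext
            Ec[j] = e
            f = Hp[j] - gop - gext
            if Fp[j] - gext > f:
                f = Fp[j] - gext
            Fc[j] = f
            h = Hp[j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hc[j] = h
            if h > best:
                best = h
        Hp = Hc
        Fp = Fc
    return best


@njit(cache=True)
def nw_fill(S, gop, gext):
    """Global (Needleman-Wunsch) affine alignment over a column-score matrix.

    S[i, j] is the score of aligning row-object i with column-object j.
    Returns (score, pointer matrix) where pointers encode 1=diag, 2=up
    (gap in columns), 3=left (gap in rows), per DP layer packed as
    ptr[layer, i, j] with layers M/Ix/Iy.
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in second (consumes first/rows)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in first (consumes second/cols)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gop - gext * i
        ptr[1, i, 0] = 2
    for j in range(1, m + 1):
        Iy[0, j] = -gop - gext * j
        ptr[2, 0, j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M layer
            best = M[i - 1, j - 1]
            p = 1
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 2
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 3
            M[i, j] = best + S[i - 1, j - 1]
            ptr[0, i, j] = p
            # Ix: consume row i (gap in columns)
            best = M[i - 1, j] - gop - gext
            p = 1
            if Ix[i - 1, j] - gext > best:
                best = Ix[i - 1, j] - gext
                p = 2
            Ix[i, j] = best
            ptr[1, i, j] = p
            # Iy: consume column j
            best = M[i, j - 1] - gop - gext
            p = 1
            if Iy[i, j - 1] - gext > best:
                best = Iy[i, j - 1] - gext
                p = 3
            Iy[i, j] = best
            ptr[2, i, j] = p
    score = M[n, m]
    layer = 0
    if Ix[n, m] > score:
        score = Ix[n, m]
        layer = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        layer = 2
    return score, layer, ptr


@njit(cache=True)
def hmm_forward(x, odds, tMM, tMI, tMD, tIM, tII, tDM, tDD, entry, exit_, r):
    """Scaled forward pass of a local profile HMM in odds space.

    x: residue indices (len L); odds[j, a]: match emission odds (1-based j);
    transitions indexed by source column; entry/exit: begin/end linkage;
    r: flank self-loop probability (the null length parameter).
    Returns the log-odds score in nats, already corrected for the null
    length model r^L (1-r).
    """
    L = len(x)
    M = odds.shape[0] - 1  # odds has M+1 rows, row 0 unused
    Mp = np.zeros(M + 1)
    Ip = np.zeros(M + 1)
    Dp = np.zeros(M + 1)
    Np = 1.0
    Cp = 0.0
    logscale = 0.0
    for i in range(L):
        a = x[i]
        Mc = np.zeros(M + 1)
        Ic = np.zeros(M + 1)
        Dc = np.zeros(M + 1)
        Bp = Np * (1.0 - r)
        for j in range(1, M + 1):
            Mc[j] = odds[j, a] * (
                Mp[j - 1] * tMM[j - 1]
                + Ip[j - 1] * tIM[j - 1]
                + Dp[j - 1] * tDM[j - 1]
                + Bp * entry[j]
            )
            Ic[j] = Mp[j] * tMI[j] + Ip[j] * tII[j]
            Dc[j] = Mc[j - 1] * tMD[j - 1] + Dc[j - 1] * tDD[j - 1]
        Ei = 0.0
        for j in range(1, M + 1):
            Ei += Mc[j] * exit_[j]
        Nc = Np * r
        Cc = Cp * r + Ei
        # rescale
        scale = Nc + Cc
        for j in range(1, M + 1):
            scale += Mc[j] + Ic[j] + Dc[j]
        if scale <= 0.0:
            return -np.inf
        inv = 1.0 / scale
        for j in range(M + 1):
            Mc[j] *= inv
            Ic[j] *= inv
            Dc[j] *= inv
        Nc *= inv
        Cc *= inv
        logscale += np.log(scale)
        Mp, Ip, Dp, Np, Cp = Mc, Ic, Dc, Nc, Cc
    p = Cp * (1.0 - r)
    if p <= 0.0:
        return -np.inf
    null = L * np.log(r) + np.log(1.0 - r)
    return np.log(p) + logscale - null


@njit(cache=True)
def hmm_forward_batch(xcat, offsets, odds, tMM, tMI, tMD, tIM, tII, tDM, tDD,
                      entry, exit_):
    """Forward scores for many sequences packed into one code array."""
    n = len(offsets) - 1
    out = np.empty(n)
    for i in range(n):
        x = xcat[offsets[i]:offsets[i + 1]]
        L = len(x)
        r = L / (L + 1.0)
        out[i] = hmm_forward(x, odds, tMM, tMI, tMD, tIM, tII, tDM, tDD,
                             entry, exit_, r)
    return out


@njit(cache=True)
def hmm_viterbi(x, lodds, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, lentry, lexit, lr, l1r):
    """Log-space Viterbi with start-coordinate tracking.

    Returns (score_nats_null_corrected, qstart, qend, mstart, mend),
    0-based half-open on the sequence, 1-based inclusive on model columns.
    """
    L = len(x)
    M = lodds.shape[0] - 1
    Mp = np.full(M + 1, NEG)
    Ip = np.full(M + 1, NEG)
    Dp = np.full(M + 1, NEG)
    # start trackers: (seq pos, model col) where the match region began
    MpQ = np.zeros(M + 1, dtype=np.int64)
    MpJ = np.zeros(M + 1, dtype=np.int64)
    IpQ = np.zeros(M + 1, dtype=np.int64)
    IpJ = np.zeros(M + 1, dtype=np.int64)
    DpQ = np.zeros(M + 1, dtype=np.int64)
    DpJ = np.zeros(M + 1, dtype=np.int64)
    lNp = 0.0
    best = NEG
    bq0 = bq1 = bj0 = bj1 = 0
    for i in range(L):
        a = x[i]
        Mc = np.full(M + 1, NEG)
        Ic = np.full(M + 1, NEG)
        Dc = np.full(M + 1, NEG)
        McQ = np.zeros(M + 1, dtype=np.int64)
        McJ = np.zeros(M + 1, dtype=np.int64)
        IcQ = np.zeros(M + 1, dtype=np.int64)
        IcJ = np.zeros(M + 1, dtype=np.int64)
        DcQ = np.zeros(M + 1, dtype=np.int64)
        DcJ = np.zeros(M + 1, dtype=np.int64)
        lBp = lNp + l1r
        for j in range(1, M + 1):
            v = lBp + lentry[j]
            q0, j0 = i, j
            c = Mp[j - 1] + ltMM[j - 1]
            if c > v:
                v, q0, j0 = c, MpQ[j - 1], MpJ[j - 1]
            c = Ip[j - 1] + ltIM[j - 1]
            if c > v:
                v, q0, j0 = c, IpQ[j - 1], IpJ[j - 1]
            c = Dp[j - 1] + ltDM[j - 1]
            if c > v:
                v, q0, j0 = c, DpQ[j - 1], DpJ[j - 1]
            Mc[j] = v + lodds[j, a]
            McQ[j], McJ[j] = q0, j0
            v = Mp[j] + ltMI[j]
            q0, j0 = MpQ[j], MpJ[j]
            c = Ip[j] + ltII[j]
            if c > v:
                v, q0, j0 = c, IpQ[j], IpJ[j]
            Ic[j] = v
            IcQ[j], IcJ[j] = q0, j0
            v = Mc[j - 1] + ltMD[j - 1]
            q0, j0 = McQ[j - 1], McJ[j - 1]
            c = Dc[j - 1] + ltDD[j - 1]
            if c > v:
                v, q0, j0 = c, DcQ[j - 1], DcJ[j - 1]
            Dc[j] = v
            DcQ[j], DcJ[j] = q0, j0
        for j in range(1, M + 1):
            end_score = Mc[j] + lexit[j] + (L - 1 - i) * lr + l1r
            if end_score > best:
                best = end_score
                bq0, bq1, bj0, bj1 = McQ[j], i + 1, McJ[j], j
        lNp = lNp + lr
        Mp, Ip, Dp = Mc, Ic, Dc
        MpQ, MpJ, IpQ, IpJ = McQ, McJ, IcQ, IcJ
        DpQ, DpJ = DcQ, DcJ
    null = L * lr + l1r
    return best - null, bq0, bq1, bj0, bj1
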