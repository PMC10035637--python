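"""Numba kernels for the profile-HMM forward and Viterbi dynamic programs.

State layout (plan7-like, no flanking random-sequence states):
node index j runs 0..L; M_0 is the begin state, a transition out of node L's
M/I/D into "M_{L+1}" is the end transition. Delete states exist for j=1..L;
insert states for j=0..L. Transition log-probabilities arrive as a (9, L+1)
array indexed by source node j, rows ordered MM, MI, MD, IM, II, ID, DM, DI,
DD; structurally impossible transitions hold -inf.

All arithmetic is in natural-log space.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf

# transition row indices
MM, MI, MD, IM, II, ID, DM, DI, DD = range(9)


@njit(cache=True, inline="always")
def _lse3(a, b, c):
    m = a
    if b > m:
        m = b
    if c > m:
        m = c
    if m == NEG_INF:
        return NEG_INF
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(c - m))


@njit(cache=True)
def forward_logprob(x, lme, lie, lt):
    """Log of the total path probability of emitting query ``x`` (int codes).

    ``lme``: (L+1, A) log match emissions (row 0 unused); ``lie``: (A,) log
    insert emissions; ``lt``: (9, L+1) log transitions.
    """
    m = x.shape[0]
    L = lme.shape[0] - 1
    fM = np.full((m + 1, L + 1), NEG_INF)
    fI = np.full((m + 1, L + 1), NEG_INF)
    fD = np.full((m + 1, L + 1), NEG_INF)
    fM[0, 0] = 0.0
    for j in range(1, L + 1):
        fD[0, j] = _lse3(fM[0, j - 1] + lt[MD, j - 1],
                         fI[0, j - 1] + lt[ID, j - 1],
                         fD[0, j - 1] + lt[DD, j - 1])
    for i in range(1, m + 1):
        xi = x[i - 1]
        fI[i, 0] = lie[xi] + _lse3(fM[i - 1, 0] + lt[MI, 0],
                                   fI[i - 1, 0] + lt[II, 0],
                                   NEG_INF)
        for j in range(1, L + 1):
            fM[i, j] = lme[j, xi] + _lse3(fM[i - 1, j - 1] + lt[MM, j - 1],
                                          fI[i - 1, j - 1] + lt[IM, j - 1],
                                          fD[i - 1, j - 1] + lt[DM, j - 1])
            fI[i, j] = lie[xi] + _lse3(fM[i - 1, j] + lt[MI, j],
                                       fI[i - 1, j] + lt[II, j],
                                       fD[i - 1, j] + lt[DI, j])
            fD[i, j] = _lse3(fM[i, j - 1] + lt[MD, j - 1],
                             fI[i, j - 1] + lt[ID, j - 1],
                             fD[i, j - 1] + lt[DD, j - 1])
    return _lse3(fM[m, L] + lt[MM, L],
                 fI[m, L] + lt[IM, L],
                 fD[m, L] + lt[DM, L])


# predecessor / state codes used in the pointer arrays
ST_M, ST_I, ST_D = 0, 1, 2


@njit(cache=True, inline="always")
def _argmax3_mdi(a_m, a_i, a_d):
    """Max of three candidates with ties broken match > delete > insert."""
    best = a_m
    arg = ST_M
    if a_d > best:
        best = a_d
        arg = ST_D
    if a_i > best:
        best = a_i
        arg = ST_I
    return best, arg


@njit(cache=True)
def viterbi(x, lme, lie, lt):
    """Most probable path. Returns (log prob, end-state code, pM, pI, pD).

    ``pM[i, j]`` is the predecessor state code of M_j after consuming letter
    i-1 (predecessor lives at (i-1, j-1)); ``pI`` at (i-1, j); ``pD`` at
    (i, j-1).
    """
    m = x.shape[0]
    L = lme.shape[0] - 1
    vM = np.full((m + 1, L + 1), NEG_INF)
    vI = np.full((m + 1, L + 1), NEG_INF)
    vD = np.full((m + 1, L + 1), NEG_INF)
    pM = np.zeros((m + 1, L + 1), dtype=np.int8)
    pI = np.zeros((m + 1, L + 1), dtype=np.int8)
    pD = np.zeros((m + 1, L + 1), dtype=np.int8)
    vM[0, 0] = 0.0
    for j in range(1, L + 1):
        best, arg = _argmax3_mdi(vM[0, j - 1] + lt[MD, j - 1],
                                 vI[0, j - 1] + lt[ID, j - 1],
                                 vD[0, j - 1] + lt[DD, j - 1])
        vD[0, j] = best
        pD[0, j] = arg
    for i in range(1, m + 1):
        xi = x[i - 1]
        best, arg = _argmax3_mdi(vM[i - 1, 0] + lt[MI, 0],
                                 vI[i - 1, 0] + lt[II, 0],
                                 NEG_INF)
        vI[i, 0] = lie[xi] + best
        pI[i, 0] = arg
        for j in range(1, L + 1):
            best, arg = _argmax3_mdi(vM[i - 1, j - 1] + lt[MM, j - 1],
                                     vI[i - 1, j - 1] + lt[IM, j - 1],
                                     vD[i - 1, j - 1] + lt[DM, j - 1])
            vM[i, j] = lme[j, xi] + best
            pM[i, j] = arg
            best, arg = _argmax3_mdi(vM[i - 1, j] + lt[MI, j],
                                     vI[i - 1, j] + lt[II, j],
                                     vD[i - 1, j] + lt[DI, j])
            vI[i, j] = lie[xi] + best
            pI[i, j] = arg
            best, arg = _argmax3_mdi(vM[i, j - 1] + lt[MD, j - 1],
                                     vI[i, j - 1] + lt[ID, j - 1],
                                     vD[i, j - 1] + lt[DD, j - 1])
            vD[i, j] = best
            pD[i, j] = arg
    best, arg = _argmax3_mdi(vM[m, L] + lt[MM, L],
                             vI[m, L] + lt[IM, L],
                             vD[m, L] + lt[DM, L])
    return best, arg, pM, pI, pD


@njit(cache=True)
def trace_dp_matrix(m, n, edge_x, edge_y, edge_w):
    """Fill the O(mn) maximum-weight non-crossing trace table.

    D[x, y] = best total weight using query letters < x and backbone columns
    < y (1-based table indices); unmatched positions cost nothing.
    """
    D = np.zeros((m + 1, n + 1))
    W = np.full((m + 1, n + 1), NEG_INF)
    for e in range(edge_x.shape[0]):
        W[edge_x[e] + 1, edge_y[e] + 1] = edge_w[e]
    for x in range(1, m + 1):
        for y in range(1, n + 1):
            best = D[x - 1, y]
            if D[x, y - 1] > best:
                best = D[x, y - 1]
            if W[x, y] != NEG_INF:
                cand = D[x - 1, y - 1] + W[x, y]
                if cand > best:
                    best = cand
            D[x, y] = best
    return D, W
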