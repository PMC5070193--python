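"""Numba kernels: profile-HMM dynamic programming, Smith-Waterman,
distance matrices and neighbor joining.

All HMM kernels work in natural-log odds space (conversion to bits happens
in the calling module).  Sequences are int8-encoded over the 21-letter
alphabet (X = 20); gaps in encoded alignments are -1.

Tie-breaking in every max is by fixed move order M > D > I (the first
candidate wins on equality), which makes tracebacks deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30

# pointer codes for the viterbi traceback
P_NONE = 0
P_MM = 1   # M[i-1][j-1] -> M
P_IM = 2   # I[i-1][j-1] -> M
P_DM = 3   # D[i-1][j-1] -> M
P_START = 4  # B -> M1 / B -> D1 chain start
P_MI = 5   # M[i][j-1] -> I
P_II = 6   # I[i][j-1] -> I
P_MD = 7   # M[i-1][j] -> D
P_DD = 8   # D[i-1][j] -> D


@njit(cache=True, inline="always")
def _delete_entries(tmm, tmd, tdm, tdd):
    """ln-probability of the composite entry B -> D1..D_{i-1} -> M_i.

    Indexed by model position i (1-based); entry[1] is the plain B -> M1
    move.  Anchoring entries at the first emitted residue keeps every
    (envelope, state path) pair counted exactly once and excludes
    zero-emission paths.
    """
    L = tmm.shape[0]
    entry = np.full(L + 1, NEG_INF)
    entry[1] = tmm[0]
    acc = tmd[0]
    for i in range(2, L + 1):
        entry[i] = acc + tdm[i - 1]
        acc += tdd[i - 1]
    return entry


@njit(cache=True)
def viterbi_glocal(me_lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq):
    """Glocal (model-global, sequence-local) Viterbi.

    Returns (score_nats, end_j, end_state, VM, VI, VD, PM, PI, PD) where
    end_state is 0 for M_L and 1 for D_L and the P* matrices hold pointer
    codes for the traceback.
    """
    L = me_lo.shape[0]
    n = seq.shape[0]
    entry = _delete_entries(tmm, tmd, tdm, tdd)
    VM = np.full((L + 1, n + 1), NEG_INF)
    VI = np.full((L + 1, n + 1), NEG_INF)
    VD = np.full((L + 1, n + 1), NEG_INF)
    PM = np.zeros((L + 1, n + 1), dtype=np.int8)
    PI = np.zeros((L + 1, n + 1), dtype=np.int8)
    PD = np.zeros((L + 1, n + 1), dtype=np.int8)

    for j in range(1, n + 1):
        a = seq[j - 1]
        for i in range(1, L + 1):
            # match state: best of the in-alignment moves and a fresh
            # entry (B -> M1 or B -> D..D -> M_i) with the flank free
            best = entry[i]
            ptr = P_START
            if i > 1:
                alt = VM[i - 1, j - 1] + tmm[i - 1]
                if alt > best:
                    best = alt
                    ptr = P_MM
                alt = VD[i - 1, j - 1] + tdm[i - 1]
                if alt > best:
                    best = alt
                    ptr = P_DM
                alt = VI[i - 1, j - 1] + tim[i - 1]
                if alt > best:
                    best = alt
                    ptr = P_IM
            VM[i, j] = best + me_lo[i - 1, a]
            PM[i, j] = ptr
            # delete state (same j); only reachable after an emission
            if i > 1:
                best = VM[i - 1, j] + tmd[i - 1]
                ptr = P_MD
                alt = VD[i - 1, j] + tdd[i - 1]
                if alt > best:
                    best = alt
                    ptr = P_DD
                VD[i, j] = best
                PD[i, j] = ptr
            # insert state I_i (emission log-odds 0 vs background)
            if 1 <= i <= L - 1:
                best = VM[i, j - 1] + tmi[i]
                ptr = P_MI
                alt = VI[i, j - 1] + tii[i]
                if alt > best:
                    best = alt
                    ptr = P_II
                VI[i, j] = best
                PI[i, j] = ptr
    # every path emits at least one residue by construction
    best = NEG_INF
    end_j = 0
    end_state = 0
    for j in range(1, n + 1):
        if VM[L, j] > best:
            best = VM[L, j]
            end_j = j
            end_state = 0
        if VD[L, j] > best:
            best = VD[L, j]
            end_j = j
            end_state = 1
    return best, end_j, end_state, VM, VI, VD, PM, PI, PD


@njit(cache=True)
def viterbi_score(me_lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq):
    """Score-only glocal Viterbi (rolling rows, no traceback)."""
    L = me_lo.shape[0]
    n = seq.shape[0]
    vm_prev = np.full(L + 1, NEG_INF)
    vi_prev = np.full(L + 1, NEG_INF)
    vd_prev = np.full(L + 1, NEG_INF)
    vm = np.full(L + 1, NEG_INF)
    vi = np.full(L + 1, NEG_INF)
    vd = np.full(L + 1, NEG_INF)
    entry = _delete_entries(tmm, tmd, tdm, tdd)
    best_all = NEG_INF
    for j in range(1, n + 1):
        a = seq[j - 1]
        for i in range(1, L + 1):
            best = entry[i]
            if i > 1:
                alt = vm_prev[i - 1] + tmm[i - 1]
                if alt > best:
                    best = alt
                alt = vd_prev[i - 1] + tdm[i - 1]
                if alt > best:
                    best = alt
                alt = vi_prev[i - 1] + tim[i - 1]
                if alt > best:
                    best = alt
            vm[i] = best + me_lo[i - 1, a]
            if i > 1:
                best = vm[i - 1] + tmd[i - 1]
                alt = vd[i - 1] + tdd[i - 1]
                if alt > best:
                    best = alt
                vd[i] = best
            else:
                vd[i] = NEG_INF
            if 1 <= i <= L - 1:
                best = vm_prev[i] + tmi[i]
                alt = vi_prev[i] + tii[i]
                if alt > best:
                    best = alt
                vi[i] = best
            else:
                vi[i] = NEG_INF
        if vm[L] > best_all:
            best_all = vm[L]
        if vd[L] > best_all:
            best_all = vd[L]
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
    return best_all


@njit(cache=True, inline="always")
def _lse(a, b):
    if a < b:
        a, b = b, a
    if b <= NEG_INF / 2:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def forward_glocal(me_lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq):
    """Glocal forward score in nats (sum over paths and envelopes)."""
    L = me_lo.shape[0]
    n = seq.shape[0]
    fm_prev = np.full(L + 1, NEG_INF)
    fi_prev = np.full(L + 1, NEG_INF)
    fd_prev = np.full(L + 1, NEG_INF)
    fm = np.full(L + 1, NEG_INF)
    fi = np.full(L + 1, NEG_INF)
    fd = np.full(L + 1, NEG_INF)
    entry = _delete_entries(tmm, tmd, tdm, tdd)
    total = NEG_INF
    for j in range(1, n + 1):
        a = seq[j - 1]
        for i in range(1, L + 1):
            s = entry[i]
            if i > 1:
                s = _lse(s, _lse(fm_prev[i - 1] + tmm[i - 1],
                                 fd_prev[i - 1] + tdm[i - 1]))
                s = _lse(s, fi_prev[i - 1] + tim[i - 1])
            fm[i] = s + me_lo[i - 1, a]
            if i > 1:
                fd[i] = _lse(fm[i - 1] + tmd[i - 1], fd[i - 1] + tdd[i - 1])
            else:
                fd[i] = NEG_INF
            if 1 <= i <= L - 1:
                fi[i] = _lse(fm_prev[i] + tmi[i], fi_prev[i] + tii[i])
            else:
                fi[i] = NEG_INF
        total = _lse(total, _lse(fm[L], fd[L]))
        fm_prev, fm = fm, fm_prev
        fi_prev, fi = fi, fi_prev
        fd_prev, fd = fd, fd_prev
    return total


# ---------------------------------------------------------------------------
# Smith-Waterman (affine, score-only)

@njit(cache=True)
def sw_score(a, b, submat, gap_open, gap_extend):
    """Local alignment raw score; gap of length k costs open + (k-1)*extend."""
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1)
    e_prev = np.zeros(m + 1)
    h = np.zeros(m + 1)
    e = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        f = 0.0
        h[0] = 0.0
        e[0] = 0.0
        ai = a[i - 1]
        for j in range(1, m + 1):
            eij = h_prev[j] - gap_open
            alt = e_prev[j] - gap_extend
            if alt > eij:
                eij = alt
            e[j] = eij
            fij = h[j - 1] - gap_open
            alt = f - gap_extend
            if alt > fij:
                fij = alt
            f = fij
            hij = h_prev[j - 1] + submat[ai, b[j - 1]]
            if eij > hij:
                hij = eij
            if fij > hij:
                hij = fij
            if hij < 0.0:
                hij = 0.0
            h[j] = hij
            if hij > best:
                best = hij
        h_prev, h = h, h_prev
        e_prev, e = e, e_prev
    return best


@njit(cache=True)
def sw_all_pairs(padded, lengths, submat, gap_open, gap_extend):
    """Raw SW score for every unordered pair of the padded sequence block."""
    n = padded.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = sw_score(padded[i, :lengths[i]], padded[j, :lengths[j]],
                         submat, gap_open, gap_extend)
            out[i, j] = s
            out[j, i] = s
    return out


# ---------------------------------------------------------------------------
# Distances and neighbor joining

@njit(cache=True)
def pdist_matrix(enc):
    """p-distance matrix of an encoded alignment (gap = -1).

    Pairs with zero shared non-gap columns get distance = 1 - 1/ncols
    sentinel-free maximum (they are effectively saturated).
    """
    n, L = enc.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            diff = 0
            for k in range(L):
                ai = enc[i, k]
                aj = enc[j, k]
                if ai >= 0 and aj >= 0:
                    shared += 1
                    if ai != aj:
                        diff += 1
            if shared == 0:
                p = 1.0
            else:
                p = diff / shared
            out[i, j] = p
            out[j, i] = p
    return out


@njit(cache=True)
def nj_merges(D0):
    """Saitou-Nei neighbor joining on a copy of ``D0``.

    Returns (merges, blens) where ``merges[k] = (a, b)`` are node indices
    joined at step k into new node ``n + k`` (leaves are 0..n-1), and
    ``blens[k] = (len_a, len_b)``.  The last merge joins the final three
    nodes: merges[-1] holds (a, b) and the third node with its length is
    encoded in the final row of blens via index array `last`.
    """
    n = D0.shape[0]
    total = 2 * n - 2
    D = np.zeros((total, total))
    D[:n, :n] = D0
    active = np.zeros(total, dtype=np.bool_)
    active[:n] = True
    idx = np.empty(total, dtype=np.int64)
    merges = np.full((n - 2, 2), -1, dtype=np.int64)
    blens = np.zeros((n - 2, 2))
    last3 = np.full(3, -1, dtype=np.int64)
    last3_len = np.zeros(3)

    m = n
    nxt = n
    for step in range(n - 3):
        # collect active indices
        cnt = 0
        for i in range(total):
            if active[i]:
                idx[cnt] = i
                cnt += 1
        r = np.zeros(cnt)
        for ii in range(cnt):
            s = 0.0
            for jj in range(cnt):
                s += D[idx[ii], idx[jj]]
            r[ii] = s
        best = 1.0e300
        bi = 0
        bj = 1
        for ii in range(cnt):
            for jj in range(ii + 1, cnt):
                q = (cnt - 2) * D[idx[ii], idx[jj]] - r[ii] - r[jj]
                if q < best:
                    best = q
                    bi = ii
                    bj = jj
        a = idx[bi]
        b = idx[bj]
        dab = D[a, b]
        la = 0.5 * dab + (r[bi] - r[bj]) / (2.0 * (cnt - 2))
        lb = dab - la
        if la < 0.0:
            la = 0.0
        if lb < 0.0:
            lb = 0.0
        merges[step, 0] = a
        merges[step, 1] = b
        blens[step, 0] = la
        blens[step, 1] = lb
        new = nxt
        nxt += 1
        for ii in range(cnt):
            k = idx[ii]
            if k != a and k != b:
                d = 0.5 * (D[a, k] + D[b, k] - dab)
                if d < 0.0:
                    d = 0.0
                D[new, k] = d
                D[k, new] = d
        active[a] = False
        active[b] = False
        active[new] = True
        m -= 1
    # final three active nodes joined at a star
    cnt = 0
    for i in range(total):
        if active[i]:
            last3[cnt] = i
            cnt += 1
    a, b, c = last3[0], last3[1], last3[2]
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    last3_len[0] = la if la > 0.0 else 0.0
    last3_len[1] = lb if lb > 0.0 else 0.0
    last3_len[2] = lc if lc > 0.0 else 0.0
    return merges, blens, last3, last3_len
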