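"""Numba-compiled inner loops.

Everything here works on flat numpy arrays; the object-level wrappers live in
:mod:`phasekit.pbwt`, :mod:`phasekit.lsm` and :mod:`phasekit.engine`.
All kernels are deterministic; randomness enters only through pre-drawn
uniform arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# PBWT construction (Durbin's single-sweep prefix/divergence update)
# ---------------------------------------------------------------------------


@njit(cache=True)
def pbwt_build_kernel(H, stored_sites):
    """Build prefix (A), divergence (D) and locator (I) arrays.

    H: uint8 [M, L] binary haplotypes.  stored_sites: sorted site indices at
    which the arrays are retained.  Arrays stored at site l are sorted by the
    reversed prefix over sites [0, l]; D[r] is the start of the match between
    ranks r and r-1 (D[0] == l + 1).
    """
    M, L = H.shape
    n_store = stored_sites.shape[0]
    A = np.empty((n_store, M), np.int32)
    D = np.empty((n_store, M), np.int32)
    I = np.empty((n_store, M), np.int32)
    a = np.empty(M, np.int32)
    d = np.zeros(M, np.int32)
    for m in range(M):
        a[m] = m
    a0 = np.empty(M, np.int32)
    a1 = np.empty(M, np.int32)
    d0 = np.empty(M, np.int32)
    d1 = np.empty(M, np.int32)
    si = 0
    for l in range(L):
        u = 0
        v = 0
        p = l + 1
        q = l + 1
        for r in range(M):
            h = a[r]
            dd = d[r]
            if dd > p:
                p = dd
            if dd > q:
                q = dd
            if H[h, l] == 0:
                a0[u] = h
                d0[u] = p
                u += 1
                p = 0
            else:
                a1[v] = h
                d1[v] = q
                v += 1
                q = 0
        for r in range(u):
            a[r] = a0[r]
            d[r] = d0[r]
        for r in range(v):
            a[u + r] = a1[r]
            d[u + r] = d1[r]
        if si < n_store and stored_sites[si] == l:
            for r in range(M):
                A[si, r] = a[r]
                D[si, r] = d[r]
                I[si, a[r]] = r
            si += 1
    return A, D, I


# ---------------------------------------------------------------------------
# Conditioning-set collection (greedy longest-prefix neighbours, batched)
# ---------------------------------------------------------------------------


@njit(cache=True)
def collect_neighbors_kernel(A, D, I, slot, hap, P, excluded, out_mask):
    """Mark up to P nearest-by-match neighbours of ``hap`` at stored ``slot``.

    Greedy walk away from the haplotype's rank, picking at each step the side
    (up/down) with the longer shared prefix (smaller match start); ties go up.
    Excluded haplotypes are skipped but their divergence still truncates the
    running match of everything beyond them.
    """
    M = A.shape[1]
    r = I[slot, hap]
    # lazily advanced up/down candidates
    cu = r
    su = 0
    up_rank = -1
    up_start = 0
    cd = r
    sd = 0
    down_rank = -1
    down_start = 0
    taken = 0
    while taken < P:
        if up_rank < 0:
            while cu > 0:
                if D[slot, cu] > su:
                    su = D[slot, cu]
                cu -= 1
                if not excluded[A[slot, cu]] and not out_mask[A[slot, cu]]:
                    up_rank = cu
                    up_start = su
                    break
        if down_rank < 0:
            while cd < M - 1:
                cd += 1
                if D[slot, cd] > sd:
                    sd = D[slot, cd]
                if not excluded[A[slot, cd]] and not out_mask[A[slot, cd]]:
                    down_rank = cd
                    down_start = sd
                    break
        if up_rank < 0 and down_rank < 0:
            break
        use_up = down_rank < 0 or (up_rank >= 0 and up_start <= down_start)
        if use_up:
            out_mask[A[slot, up_rank]] = True
            up_rank = -1
        else:
            out_mask[A[slot, down_rank]] = True
            down_rank = -1
        taken += 1
    return taken


@njit(cache=True)
def collect_window_kernel(A, D, I, slots, h1, h2, P, excluded):
    """Union of per-stored-site neighbour sets for both target haplotypes."""
    M = A.shape[1]
    out_mask = np.zeros(M, np.bool_)
    for s in slots:
        tmp = np.zeros(M, np.bool_)
        collect_neighbors_kernel(A, D, I, s, h1, P, excluded, tmp)
        collect_neighbors_kernel(A, D, I, s, h2, P, excluded, tmp)
        for m in range(M):
            if tmp[m]:
                out_mask[m] = True
    return out_mask


# ---------------------------------------------------------------------------
# Long genotype matches (IBD2 detection, wildcard-missing equality runs)
# ---------------------------------------------------------------------------


@njit(cache=True)
def ibd2_scan_kernel(codes, pos, min_span, out, count_only):
    """All maximal pairwise genotype-equality runs spanning >= min_span bp.

    Missing genotypes (< 0) match anything.  A run covering sites [a, b]
    spans pos[b] - pos[a] + 1 bp.  ``out`` receives rows (i, j, a, b).
    """
    N, L = codes.shape
    n = 0
    for i in range(N):
        for j in range(i + 1, N):
            start = 0
            for l in range(L):
                ci = codes[i, l]
                cj = codes[j, l]
                if ci != cj and ci >= 0 and cj >= 0:
                    if l > start and pos[l - 1] - pos[start] + 1 >= min_span:
                        if not count_only:
                            out[n, 0] = i
                            out[n, 1] = j
                            out[n, 2] = start
                            out[n, 3] = l - 1
                        n += 1
                    start = l + 1
            if start < L and pos[L - 1] - pos[start] + 1 >= min_span:
                if not count_only:
                    out[n, 0] = i
                    out[n, 1] = j
                    out[n, 2] = start
                    out[n, 3] = L - 1
                n += 1
    return n


# ---------------------------------------------------------------------------
# PBWT-guided haplotype initialization
# ---------------------------------------------------------------------------


@njit(cache=True)
def init_phase_kernel(codes, freq, U):
    """Left-to-right initialization sweep.

    At each site the known alleles (homozygous: -1/+1) are placed and the
    unknown het alleles (0) imputed by copying the nearest haplotype with a
    known allele in the previous-site prefix array; complementarity at hets
    is then enforced by flipping the copy with the shorter divergence-backed
    match.  Missing genotypes and the first site draw from allele frequency.

    codes: int8 [N, L]; freq: float64 [L]; U: float64 [2N, L] uniforms.
    Returns uint8 [2N, L] haplotypes.
    """
    N, L = codes.shape
    M = 2 * N
    hap = np.zeros((M, L), np.uint8)
    a = np.empty(M, np.int32)
    d = np.zeros(M, np.int32)
    for m in range(M):
        a[m] = m
    a0 = np.empty(M, np.int32)
    a1 = np.empty(M, np.int32)
    d0 = np.empty(M, np.int32)
    d1 = np.empty(M, np.int32)
    b = np.zeros(M, np.int8)
    support = np.zeros(M, np.int32)
    prev_rank = np.empty(M, np.int32)
    prev_val = np.empty(M, np.int8)
    prev_start = np.empty(M, np.int32)
    next_rank = np.empty(M, np.int32)
    next_val = np.empty(M, np.int8)
    next_start = np.empty(M, np.int32)
    imputed = np.empty(M, np.int8)
    for l in range(L):
        for i in range(N):
            c = codes[i, l]
            if c == 0:
                b[2 * i] = -1
                b[2 * i + 1] = -1
            elif c == 2:
                b[2 * i] = 1
                b[2 * i + 1] = 1
            elif c < 0:
                b[2 * i] = 1 if U[2 * i, l] < freq[l] else -1
                b[2 * i + 1] = 1 if U[2 * i + 1, l] < freq[l] else -1
            else:
                b[2 * i] = 0
                b[2 * i + 1] = 0
        if l == 0:
            for i in range(N):
                if b[2 * i] == 0:
                    if U[2 * i, l] < 0.5:
                        b[2 * i] = -1
                        b[2 * i + 1] = 1
                    else:
                        b[2 * i] = 1
                        b[2 * i + 1] = -1
            for m in range(M):
                support[m] = 0
        else:
            # nearest known neighbour above (lower rank) in permuted order
            last = -1
            lastv = np.int8(0)
            runmax = 0
            for r in range(M):
                if r > 0 and d[r] > runmax:
                    runmax = d[r]
                prev_rank[r] = last
                prev_val[r] = lastv
                prev_start[r] = runmax
                if b[a[r]] != 0:
                    last = r
                    lastv = b[a[r]]
                    runmax = 0
            # nearest known neighbour below (higher rank)
            last = -1
            lastv = np.int8(0)
            runmax = 0
            for r in range(M - 1, -1, -1):
                if r < M - 1 and d[r + 1] > runmax:
                    runmax = d[r + 1]
                next_rank[r] = last
                next_val[r] = lastv
                next_start[r] = runmax
                if b[a[r]] != 0:
                    last = r
                    lastv = b[a[r]]
                    runmax = 0
            for r in range(M):
                m = a[r]
                if b[m] != 0:
                    imputed[r] = b[m]
                    support[m] = l + 1
                    continue
                has_up = prev_rank[r] >= 0
                has_down = next_rank[r] >= 0
                if has_up and has_down:
                    du = r - prev_rank[r]
                    dn = next_rank[r] - r
                    use_up = du <= dn
                elif has_up:
                    use_up = True
                elif has_down:
                    use_up = False
                else:
                    imputed[r] = 1 if U[m, l] < freq[l] else -1
                    support[m] = 0
                    continue
                if use_up:
                    imputed[r] = prev_val[r]
                    support[m] = l - prev_start[r]
                else:
                    imputed[r] = next_val[r]
                    support[m] = l - next_start[r]
            for r in range(M):
                b[a[r]] = imputed[r]
        # complementarity at hets: the two copies must differ
        for i in range(N):
            if codes[i, l] == 1:
                x = b[2 * i]
                y = b[2 * i + 1]
                if x == y:
                    if support[2 * i] < support[2 * i + 1]:
                        b[2 * i] = -x
                    else:
                        b[2 * i + 1] = -y
        for m in range(M):
            hap[m, l] = 1 if b[m] == 1 else 0
        # advance the PBWT to include site l
        u = 0
        v = 0
        p = l + 1
        q = l + 1
        for r in range(M):
            h = a[r]
            dd = d[r]
            if dd > p:
                p = dd
            if dd > q:
                q = dd
            if hap[h, l] == 0:
                a0[u] = h
                d0[u] = p
                u += 1
                p = 0
            else:
                a1[v] = h
                d1[v] = q
                v += 1
                q = 0
        for r in range(u):
            a[r] = a0[r]
            d[r] = d0[r]
        for r in range(v):
            a[u + r] = a1[r]
            d[u + r] = d1[r]
    return hap


# ---------------------------------------------------------------------------
# Diploid Li-Stephens HMM over a flattened genotype graph
# ---------------------------------------------------------------------------
#
# Flat graph layout (see genotype_graph.GenotypeGraph.flatten):
#   seg_off[n_seg+1]   window-local site span of each segment
#   amb_off[n_seg+1]   offsets into amb_pos (ambiguous-site indices)
#   cfg_off[n_seg+1]   offsets into the per-config weight array cfg_w
#   cfg_dat_off[n_seg] start of segment s in cfg_h1/cfg_h2; config j,
#                      ambiguous slot t -> cfg_dat_off[s] + j*A_s + t
#   bnd_off[n_seg]     start of boundary s (between s and s+1) in bnd_f,
#                      row-major [C_s, C_{s+1}]; bnd_trivial flags all-ones
# Conditioning haplotypes are deduplicated: cond [Ku, Lw] with multiplicity
# weights w (sum w == K).  Transitions: stay te = exp(-rho/K), switch into
# state k is ts*w[k] with ts = (1-te)/K, which is exactly the chain obtained
# by merging duplicated conditioning haplotypes.


@njit(cache=True, fastmath=True)
def _seg_emissions(s, seg_off, amb_off, amb_pos, cfg_off, cfg_dat_off,
                   cfg_h1, cfg_h2, cfg_w, fixed_mask, fixed_h, cond,
                   e_match, e_mis, E1, E2):
    """Per-config per-state emission products for segment s (into E1/E2).

    The fixed-site product is accumulated in log space and renormalized by
    its maximum (long homozygous stretches otherwise underflow when every
    conditioning haplotype mismatches).  Returns (C, logshift): the true
    emission carries an extra factor exp(logshift) per haplotype chain.
    """
    Ku = cond.shape[0]
    C = cfg_off[s + 1] - cfg_off[s]
    A = amb_off[s + 1] - amb_off[s]
    le_match = np.log(e_match)
    le_mis = np.log(e_mis)
    lfix = np.zeros(Ku, np.float64)
    for site in range(seg_off[s], seg_off[s + 1]):
        if fixed_mask[site]:
            h = fixed_h[site]
            for k in range(Ku):
                lfix[k] += le_match if cond[k, site] == h else le_mis
    m = lfix[0]
    for k in range(1, Ku):
        if lfix[k] > m:
            m = lfix[k]
    fix = np.empty(Ku, np.float64)
    for k in range(Ku):
        fix[k] = np.exp(lfix[k] - m)
    for c in range(C):
        wc = cfg_w[cfg_off[s] + c]
        base = cfg_dat_off[s] + c * A
        for k in range(Ku):
            p1 = fix[k]
            p2 = fix[k]
            for t in range(A):
                site = amb_pos[amb_off[s] + t]
                ck = cond[k, site]
                p1 *= e_match if ck == cfg_h1[base + t] else e_mis
                p2 *= e_match if ck == cfg_h2[base + t] else e_mis
            E1[c, k] = wc * p1
            E2[c, k] = p2
    return C, m


@njit(cache=True, fastmath=True)
def _apply_trans_fwd(pre, te, ts, w, out):
    """out = (T x T) applied to pre over both state axes (forward).

    pre/out: flat [Ku*Ku] row-major (k1, k2).  Switch into state k carries
    its multiplicity weight w[k].
    """
    Ku = w.shape[0]
    colsum = np.zeros(Ku, np.float64)
    idx = 0
    for k1 in range(Ku):
        for k2 in range(Ku):
            colsum[k2] += pre[idx]
            idx += 1
    idx = 0
    for k1 in range(Ku):
        wk = ts * w[k1]
        for k2 in range(Ku):
            out[idx] = te * pre[idx] + wk * colsum[k2]
            idx += 1
    idx = 0
    for k1 in range(Ku):
        tot = 0.0
        base = idx
        for k2 in range(Ku):
            tot += out[idx]
            idx += 1
        tot *= ts
        idx = base
        for k2 in range(Ku):
            out[idx] = te * out[idx] + w[k2] * tot
            idx += 1


@njit(cache=True, fastmath=True)
def _apply_trans_bwd(g, te, ts, w, out):
    """out[k] = sum_k' T(k->k') g[k'] over both axes (backward); flat."""
    Ku = w.shape[0]
    colsum = np.zeros(Ku, np.float64)
    idx = 0
    for k1 in range(Ku):
        wk = w[k1]
        for k2 in range(Ku):
            colsum[k2] += wk * g[idx]
            idx += 1
    idx = 0
    for k1 in range(Ku):
        for k2 in range(Ku):
            out[idx] = te * g[idx] + ts * colsum[k2]
            idx += 1
    idx = 0
    for k1 in range(Ku):
        tot = 0.0
        base = idx
        for k2 in range(Ku):
            tot += w[k2] * out[idx]
            idx += 1
        tot *= ts
        idx = base
        for k2 in range(Ku):
            out[idx] = te * out[idx] + tot
            idx += 1


@njit(cache=True, fastmath=True)
def lsm_forward_kernel(seg_off, amb_off, amb_pos, cfg_off, cfg_dat_off,
                       cfg_h1, cfg_h2, cfg_w, bnd_off, bnd_f, bnd_trivial,
                       fixed_mask, fixed_h, cond, w, k_tot,
                       e_match, e_mis, t_e, t_s,
                       alpha, a_off, scales):
    """Scaled forward pass; returns the log-likelihood."""
    n_seg = seg_off.shape[0] - 1
    Ku = cond.shape[0]
    kk = Ku * Ku
    Cmax = 0
    for s in range(n_seg):
        if cfg_off[s + 1] - cfg_off[s] > Cmax:
            Cmax = cfg_off[s + 1] - cfg_off[s]
    E1 = np.empty((Cmax, Ku), np.float64)
    E2 = np.empty((Cmax, Ku), np.float64)
    pre = np.empty(kk, np.float64)
    trans = np.empty(kk, np.float64)
    loglik = 0.0
    Cp = 0
    inv2 = 1.0 / (k_tot * k_tot)
    for s in range(n_seg):
        C, mshift = _seg_emissions(s, seg_off, amb_off, amb_pos, cfg_off,
                                   cfg_dat_off, cfg_h1, cfg_h2, cfg_w,
                                   fixed_mask, fixed_h, cond,
                                   e_match, e_mis, E1, E2)
        loglik += 2.0 * mshift
        base = a_off[s]
        if s == 0:
            idx = base
            for c in range(C):
                for k1 in range(Ku):
                    e1 = E1[c, k1] * w[k1] * inv2
                    for k2 in range(Ku):
                        alpha[idx] = e1 * E2[c, k2] * w[k2]
                        idx += 1
        else:
            pbase = a_off[s - 1]
            te = t_e[s - 1]
            ts = t_s[s - 1]
            if bnd_trivial[s - 1]:
                for x in range(kk):
                    pre[x] = alpha[pbase + x]
                for cp in range(1, Cp):
                    b2 = pbase + cp * kk
                    for x in range(kk):
                        pre[x] += alpha[b2 + x]
                _apply_trans_fwd(pre, te, ts, w, trans)
                idx = base
                for c in range(C):
                    x = 0
                    for k1 in range(Ku):
                        e1 = E1[c, k1]
                        for k2 in range(Ku):
                            alpha[idx] = trans[x] * e1 * E2[c, k2]
                            idx += 1
                            x += 1
            else:
                fb = bnd_off[s - 1]
                for c in range(C):
                    f0 = bnd_f[fb + c]
                    for x in range(kk):
                        pre[x] = f0 * alpha[pbase + x]
                    for cp in range(1, Cp):
                        f = bnd_f[fb + cp * C + c]
                        b2 = pbase + cp * kk
                        for x in range(kk):
                            pre[x] += f * alpha[b2 + x]
                    _apply_trans_fwd(pre, te, ts, w, trans)
                    idx = base + c * kk
                    x = 0
                    for k1 in range(Ku):
                        e1 = E1[c, k1]
                        for k2 in range(Ku):
                            alpha[idx] = trans[x] * e1 * E2[c, k2]
                            idx += 1
                            x += 1
        sc = 0.0
        for x in range(base, base + C * kk):
            sc += alpha[x]
        if sc <= 0.0:
            return -np.inf
        inv = 1.0 / sc
        for x in range(base, base + C * kk):
            alpha[x] *= inv
        scales[s] = sc
        loglik += np.log(sc)
        Cp = C
    return loglik


@njit(cache=True, fastmath=True)
def lsm_backward_kernel(seg_off, amb_off, amb_pos, cfg_off, cfg_dat_off,
                        cfg_h1, cfg_h2, cfg_w, bnd_off, bnd_f, bnd_trivial,
                        fixed_mask, fixed_h, cond, w,
                        e_match, e_mis, t_e, t_s,
                        alpha, a_off, tables, marg0):
    """Backward pass filling boundary config-pair posteriors and marg0.

    ``tables`` is flat, boundary s occupying bnd-style row-major blocks at
    bnd_off[s] (same layout as bnd_f); each block is normalized to sum 1.
    """
    n_seg = seg_off.shape[0] - 1
    Ku = cond.shape[0]
    kk = Ku * Ku
    Cmax = 0
    for s in range(n_seg):
        if cfg_off[s + 1] - cfg_off[s] > Cmax:
            Cmax = cfg_off[s + 1] - cfg_off[s]
    E1 = np.empty((Cmax, Ku), np.float64)
    E2 = np.empty((Cmax, Ku), np.float64)
    beta = np.ones((Cmax, kk), np.float64)
    beta_new = np.empty((Cmax, kk), np.float64)
    g = np.empty(kk, np.float64)
    tg = np.empty((Cmax, kk), np.float64)
    for s in range(n_seg - 2, -1, -1):
        Cn, _ = _seg_emissions(s + 1, seg_off, amb_off, amb_pos, cfg_off,
                               cfg_dat_off, cfg_h1, cfg_h2, cfg_w, fixed_mask,
                               fixed_h, cond, e_match, e_mis, E1, E2)
        C = cfg_off[s + 1] - cfg_off[s]
        te = t_e[s]
        ts = t_s[s]
        for cn in range(Cn):
            x = 0
            for k1 in range(Ku):
                e1 = E1[cn, k1]
                for k2 in range(Ku):
                    g[x] = e1 * E2[cn, k2] * beta[cn, x]
                    x += 1
            _apply_trans_bwd(g, te, ts, w, tg[cn])
        abase = a_off[s]
        fb = bnd_off[s]
        tsum = 0.0
        for c in range(C):
            off = abase + c * kk
            for cn in range(Cn):
                f = 1.0 if bnd_trivial[s] else bnd_f[fb + c * Cn + cn]
                tot = 0.0
                for x in range(kk):
                    tot += alpha[off + x] * tg[cn, x]
                tables[fb + c * Cn + cn] = f * tot
                tsum += f * tot
        if tsum > 0.0:
            inv = 1.0 / tsum
            for y in range(C * Cn):
                tables[fb + y] *= inv
        # beta recursion
        bsum = 0.0
        for c in range(C):
            f0 = 1.0 if bnd_trivial[s] else bnd_f[fb + c * Cn]
            for x in range(kk):
                beta_new[c, x] = f0 * tg[0, x]
            for cn in range(1, Cn):
                f = 1.0 if bnd_trivial[s] else bnd_f[fb + c * Cn + cn]
                for x in range(kk):
                    beta_new[c, x] += f * tg[cn, x]
            for x in range(kk):
                bsum += beta_new[c, x]
        if bsum > 0.0:
            inv = 1.0 / bsum
            for c in range(C):
                for x in range(kk):
                    beta[c, x] = beta_new[c, x] * inv
    # first-segment config marginal
    C0 = cfg_off[1] - cfg_off[0]
    msum = 0.0
    for c in range(C0):
        tot = 0.0
        off = a_off[0] + c * kk
        for x in range(kk):
            tot += alpha[off + x] * beta[c, x]
        marg0[c] = tot
        msum += tot
    if msum > 0.0:
        for c in range(C0):
            marg0[c] /= msum


@njit(cache=True, fastmath=True)
def lsm_sample_kernel(cfg_off, bnd_off, bnd_f, bnd_trivial,
                      w, t_e, t_s, alpha, a_off, uniforms, cfg_path):
    """Backward stochastic traceback through the scaled forward quantities.

    uniforms: float64 [3 * n_seg]; cfg_path (int32 [n_seg]) receives the
    sampled configuration per segment.
    """
    n_seg = cfg_off.shape[0] - 1
    nw = w.shape[0]
    Ku = nw
    # last segment: draw (c, k1, k2) proportional to alpha
    s = n_seg - 1
    C = cfg_off[s + 1] - cfg_off[s]
    base = a_off[s]
    tot = 0.0
    for x in range(C * Ku * Ku):
        tot += alpha[base + x]
    u = uniforms[3 * s] * tot
    acc = 0.0
    c_sel = C - 1
    for c in range(C):
        blk = 0.0
        for x in range(Ku * Ku):
            blk += alpha[base + c * Ku * Ku + x]
        acc += blk
        if u <= acc:
            c_sel = c
            acc -= blk
            break
        if c == C - 1:
            acc -= blk
    # k1 given c
    off = base + c_sel * Ku * Ku
    u1 = uniforms[3 * s + 1]
    rowtot = 0.0
    for x in range(Ku * Ku):
        rowtot += alpha[off + x]
    u1 *= rowtot
    acc1 = 0.0
    k1_sel = Ku - 1
    for k1 in range(Ku):
        r = 0.0
        for k2 in range(Ku):
            r += alpha[off + k1 * Ku + k2]
        acc1 += r
        if u1 <= acc1:
            k1_sel = k1
            break
    u2 = uniforms[3 * s + 2]
    rtot = 0.0
    for k2 in range(Ku):
        rtot += alpha[off + k1_sel * Ku + k2]
    u2 *= rtot
    acc2 = 0.0
    k2_sel = Ku - 1
    for k2 in range(Ku):
        acc2 += alpha[off + k1_sel * Ku + k2]
        if u2 <= acc2:
            k2_sel = k2
            break
    cfg_path[s] = c_sel
    for s in range(n_seg - 2, -1, -1):
        C = cfg_off[s + 1] - cfg_off[s]
        Cn = cfg_off[s + 2] - cfg_off[s + 1]
        base = a_off[s]
        te = t_e[s]
        ts = t_s[s]
        a1 = ts * w[k1_sel]
        a2 = ts * w[k2_sel]
        cn = c_sel
        # config totals
        tot = 0.0
        ctot = np.empty(C, np.float64)
        for c in range(C):
            off = base + c * Ku * Ku
            f = 1.0 if bnd_trivial[s] else bnd_f[bnd_off[s] + c * Cn + cn]
            sall = 0.0
            srow = 0.0  # sum over k2 at k1 = k1_sel
            scol = 0.0  # sum over k1 at k2 = k2_sel
            for k1 in range(Ku):
                for k2 in range(Ku):
                    v = alpha[off + k1 * Ku + k2]
                    sall += v
                    if k1 == k1_sel:
                        srow += v
                    if k2 == k2_sel:
                        scol += v
            val = f * (a1 * a2 * sall + a1 * te * scol + te * a2 * srow
                       + te * te * alpha[off + k1_sel * Ku + k2_sel])
            ctot[c] = val
            tot += val
        u = uniforms[3 * s] * tot
        acc = 0.0
        c_new = C - 1
        for c in range(C):
            acc += ctot[c]
            if u <= acc:
                c_new = c
                break
        off = base + c_new * Ku * Ku
        # k1 | c
        k1tot = np.empty(Ku, np.float64)
        t1 = 0.0
        for k1 in range(Ku):
            srow = 0.0
            for k2 in range(Ku):
                srow += alpha[off + k1 * Ku + k2]
            v = (a1 + (te if k1 == k1_sel else 0.0)) * (
                a2 * srow + te * alpha[off + k1 * Ku + k2_sel])
            k1tot[k1] = v
            t1 += v
        u1 = uniforms[3 * s + 1] * t1
        acc1 = 0.0
        k1_new = Ku - 1
        for k1 in range(Ku):
            acc1 += k1tot[k1]
            if u1 <= acc1:
                k1_new = k1
                break
        # k2 | c, k1
        t2 = 0.0
        k2tot = np.empty(Ku, np.float64)
        for k2 in range(Ku):
            v = alpha[off + k1_new * Ku + k2] * (
                a2 + (te if k2 == k2_sel else 0.0))
            k2tot[k2] = v
            t2 += v
        u2 = uniforms[3 * s + 2] * t2
        acc2 = 0.0
        k2_new = Ku - 1
        for k2 in range(Ku):
            acc2 += k2tot[k2]
            if u2 <= acc2:
                k2_new = k2
                break
        c_sel = c_new
        k1_sel = k1_new
        k2_sel = k2_new
        cfg_path[s] = c_sel
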