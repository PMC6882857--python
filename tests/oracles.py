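"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: PBWT arrays by
stable sorting reversed prefixes, neighbour sets by scanning all pairwise
match lengths, IBD2 runs by per-pair numpy run-finding, and HMM posteriors
by exhaustive enumeration over configuration and copying-state sequences.
"""

from itertools import product

import numpy as np

from phasekit import lsm


def pbwt_arrays_oracle(H, l):
    """(A, Dv) at site l by stable sort of reversed prefixes."""
    H = np.asarray(H)
    M = H.shape[0]
    order = sorted(range(M), key=lambda h: tuple(H[h, l::-1]))
    div = [l + 1]
    for r in range(1, M):
        a, b = order[r], order[r - 1]
        j = l + 1
        while j > 0 and H[a, j - 1] == H[b, j - 1]:
            j -= 1
        div.append(j)
    return np.array(order), np.array(div)


def match_start_oracle(H, a, b, l):
    """Start of the match between haplotypes a and b ending at site l."""
    j = l + 1
    while j > 0 and H[a, j - 1] == H[b, j - 1]:
        j -= 1
    return j


def neighbors_oracle(H, hap, l, P, exclude=frozenset()):
    """The P longest-shared-prefix neighbours at l.

    Order: longer match first (smaller start); ties prefer the up (lower
    rank) side, then smaller rank distance.
    """
    A, _ = pbwt_arrays_oracle(H, l)
    rank = {h: r for r, h in enumerate(A)}
    cands = []
    for o in range(H.shape[0]):
        if o == hap or o in exclude:
            continue
        start = match_start_oracle(H, hap, o, l)
        up = rank[o] < rank[hap]
        cands.append((start, 0 if up else 1, abs(rank[o] - rank[hap]), o))
    cands.sort()
    return [c[3] for c in cands[:P]]


def ibd2_runs_oracle(codes, pos, min_span):
    """All maximal wildcard-equality runs >= min_span bp, per pair."""
    codes = np.asarray(codes)
    pos = np.asarray(pos)
    N, L = codes.shape
    out = []
    for i in range(N):
        for j in range(i + 1, N):
            eq = (codes[i] == codes[j]) | (codes[i] < 0) | (codes[j] < 0)
            padded = np.concatenate([[False], eq, [False]]).astype(int)
            d = np.diff(padded)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            for a, b in zip(starts, ends):
                if pos[b] - pos[a] + 1 >= min_span:
                    out.append((i, j, int(a), int(b)))
    return out


def _pair_ps_factor(graph, h1, eps):
    """Phase-set factor: consecutive within-set het pairs in the same or
    adjacent segments."""
    if graph.ps is None or not graph.ps.entries:
        return 1.0
    het = set(int(h) for h in graph.het_sites())
    by_set = {}
    for site in sorted(graph.ps.entries):
        if site in het:
            by_set.setdefault(graph.ps.entries[site][0], []).append(site)
    out = 1.0
    for sites in by_set.values():
        for u, v in zip(sites[:-1], sites[1:]):
            if graph.segment_of(v) - graph.segment_of(u) > 1:
                continue
            agree = (h1[u] == h1[v]) == (
                graph.ps.entries[u][1] == graph.ps.entries[v][1])
            out *= (1.0 - eps) if agree else eps
    return out


def enumerate_hmm(graph, cond, params, cm):
    """Exhaustive diploid-LSM sums over (config path, k1 path, k2 path).

    Returns (marg0, boundary_tables, loglik) using the same model factors
    as the package (transition_probs / emission_prob scalar forms) but a
    completely independent summation path.
    """
    cond = np.asarray(cond)
    K = cond.shape[0]
    n_seg = graph.n_segments
    counts = graph.config_counts()
    n_hap = params.n_hap if params.n_hap else K + 2
    stays, sws = [], []
    for s in range(n_seg - 1):
        last = graph.seg_starts[s + 1] - 1
        first = graph.seg_starts[s + 1]
        g = max(cm[first] - cm[last], lsm.MIN_DIST_CM)
        stay, sw = lsm.transition_probs(g, K, params.ne, n_hap)
        stays.append(stay)
        sws.append(sw)
    eps = graph.ps.eps if graph.ps is not None else None

    def seg_emission(s, c, k, chain):
        lo, hi = graph.seg_starts[s], graph.seg_starts[s + 1]
        amb = list(graph.amb_sites[s])
        cfg = (graph.cfg_h1 if chain == 0 else graph.cfg_h2)[s][c]
        p = 1.0
        for site in range(lo, hi):
            if site in amb:
                h = cfg[amb.index(site)]
            elif graph.g[site] >= 0:
                h = graph.g[site] // 2
            else:
                continue
            p *= lsm.emission_prob(int(cond[k, site]), int(h), K)
        return p

    marg0 = np.zeros(counts[0])
    tables = [np.zeros((counts[s], counts[s + 1])) for s in range(n_seg - 1)]
    total = 0.0
    for cfg_path in product(*(range(c) for c in counts)):
        h1, _ = graph.pair_from_configs(cfg_path)
        psf = _pair_ps_factor(graph, h1, eps) if eps is not None else 1.0
        for k1_path in product(range(K), repeat=n_seg):
            for k2_path in product(range(K), repeat=n_seg):
                w = psf / (K * K)
                for s in range(n_seg):
                    w *= seg_emission(s, cfg_path[s], k1_path[s], 0)
                    w *= seg_emission(s, cfg_path[s], k2_path[s], 1)
                    if s:
                        w *= stays[s - 1] if k1_path[s] == k1_path[s - 1] else sws[s - 1]
                        w *= stays[s - 1] if k2_path[s] == k2_path[s - 1] else sws[s - 1]
                total += w
                marg0[cfg_path[0]] += w
                for s in range(n_seg - 1):
                    tables[s][cfg_path[s], cfg_path[s + 1]] += w
    return (marg0 / total, [t / total for t in tables], np.log(total))
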