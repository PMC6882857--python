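"""Diploid Li-Stephens HMM over a genotype graph and K conditioning haplotypes.

The chain state per segment is (configuration, copied haplotype for each of
the two target haplotypes).  Duplicated conditioning haplotypes are merged
into multiplicity-weighted states, which reproduces the plain-K chain
exactly while shrinking the quadratic part of the computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genotype_graph import GenotypeGraph

DEFAULT_NE = 15_000.0

#: floor for inter-segment genetic distances (cM); keeps the chain mixing
#: when consecutive segments share a physical position.
MIN_DIST_CM = 1e-7


@dataclass
class LsmParams:
    """Population-genetic parameters of the copying model."""

    ne: float = DEFAULT_NE
    n_hap: int = 0          # total haplotypes in the panel (for rho)

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("ne must be positive")


def theta_from_k(K: int) -> float:
    """Li-Stephens mutation parameter: inverse harmonic number of K - 1."""
    K = max(int(K), 2)
    return 1.0 / sum(1.0 / k for k in range(1, K))


def transition_probs(g_cm: float, K: int, ne: float, n_hap: int):
    """(stay, switch_each) for one inter-segment genetic distance.

    rho = 4 * Ne * Morgans / n_hap;  stay = e^(-rho/K) + (1 - e^(-rho/K))/K;
    each of the K states receives (1 - e^(-rho/K))/K switch mass, so
    stay + (K - 1) * switch_each == 1.
    """
    if g_cm < 0:
        raise ValueError("negative genetic distance")
    rho = 4.0 * ne * (g_cm / 100.0) / n_hap
    e = math.exp(-rho / K)
    switch_each = (1.0 - e) / K
    return e + switch_each, switch_each


def emission_prob(copied_allele: int, observed_allele: int, K: int) -> float:
    """Li-Stephens mutation emission for one site."""
    theta = theta_from_k(K)
    mis = 0.5 * theta / (K + theta)
    return (K / (K + theta) + mis) if copied_allele == observed_allele else mis


@dataclass
class LsmResult:
    """Forward(-backward) quantities for one individual/window."""

    graph: GenotypeGraph
    flat: object
    cond: np.ndarray            # deduplicated conditioning haplotypes
    weights: np.ndarray         # multiplicities, sum == k_total
    k_total: int
    t_e: np.ndarray
    t_s: np.ndarray
    alpha: np.ndarray
    a_off: np.ndarray
    scales: np.ndarray
    loglik: float
    boundary_posteriors: list = field(default_factory=list)
    marg0: np.ndarray = None


_ALPHA_BUF = np.empty(0)


def _workspace(size: int) -> np.ndarray:
    """Reusable forward-matrix buffer (avoids large per-call allocations).

    The returned view is invalidated by the next :func:`forward` call; an
    :class:`LsmResult` must therefore be consumed before another pass runs.
    """
    global _ALPHA_BUF
    if _ALPHA_BUF.size < size:
        _ALPHA_BUF = np.empty(int(size * 1.2))
    return _ALPHA_BUF[:size]


def _segment_distances_cm(graph: GenotypeGraph, cm: np.ndarray) -> np.ndarray:
    """Genetic distance between the last site of each segment and the first
    site of the next."""
    n_seg = graph.n_segments
    out = np.empty(max(n_seg - 1, 0))
    for s in range(n_seg - 1):
        last = graph.seg_starts[s + 1] - 1
        first = graph.seg_starts[s + 1]
        out[s] = max(cm[first] - cm[last], MIN_DIST_CM)
    return out


def _prepare(graph, cond, params, cm):
    cond = np.ascontiguousarray(cond, dtype=np.uint8)
    k_total = cond.shape[0]
    if k_total < 1:
        raise ValueError("empty conditioning set")
    # content-level dedup with multiplicities (hash rows; much faster than
    # np.unique(axis=0) at these shapes)
    seen: dict = {}
    for k in range(k_total):
        key = cond[k].tobytes()
        if key in seen:
            seen[key][1] += 1
        else:
            seen[key] = [k, 1]
    rows = sorted(seen.values())
    uniq = cond[[r[0] for r in rows]]
    counts = np.array([r[1] for r in rows], dtype=np.int64)
    flat = graph.flatten()
    dists = _segment_distances_cm(graph, cm)
    n_hap = params.n_hap if params.n_hap else k_total + 2
    t_e = np.empty(len(dists))
    for s, g in enumerate(dists):
        rho = 4.0 * params.ne * (g / 100.0) / n_hap
        t_e[s] = math.exp(-rho / k_total)
    t_s = (1.0 - t_e) / k_total
    e_mis = emission_prob(0, 1, k_total)
    e_match = emission_prob(0, 0, k_total)
    counts = counts.astype(np.float64)
    n_seg = graph.n_segments
    ku = uniq.shape[0]
    sizes = np.array([c * ku * ku for c in graph.config_counts()], dtype=np.int64)
    a_off = np.zeros(n_seg + 1, np.int64)
    np.cumsum(sizes, out=a_off[1:])
    alpha = _workspace(int(a_off[-1]))
    scales = np.empty(n_seg)
    return (flat, uniq, counts, k_total, t_e, t_s, e_match, e_mis,
            alpha, a_off, scales)


def forward(graph: GenotypeGraph, cond: np.ndarray, params: LsmParams,
            cm: np.ndarray) -> LsmResult:
    """Scaled forward pass only (enough to sample a pair)."""
    (flat, uniq, counts, k_total, t_e, t_s, e_match, e_mis,
     alpha, a_off, scales) = _prepare(graph, cond, params, cm)
    loglik = _kernels.lsm_forward_kernel(
        flat.seg_off, flat.amb_off, flat.amb_pos, flat.cfg_off,
        flat.cfg_dat_off, flat.cfg_h1, flat.cfg_h2, flat.cfg_w,
        flat.bnd_off, flat.bnd_f, flat.bnd_trivial,
        flat.fixed_mask, flat.fixed_h, uniq, counts, float(k_total),
        e_match, e_mis, t_e, t_s, alpha, a_off, scales)
    if not np.isfinite(loglik):
        raise FloatingPointError("forward pass underflowed despite scaling")
    return LsmResult(graph=graph, flat=flat, cond=uniq, weights=counts,
                     k_total=k_total, t_e=t_e, t_s=t_s, alpha=alpha,
                     a_off=a_off, scales=scales, loglik=loglik)


def forward_backward(graph: GenotypeGraph, cond: np.ndarray, params: LsmParams,
                     cm: np.ndarray, ps_constraints=None) -> LsmResult:
    """Forward-backward pass; fills boundary config-pair posteriors.

    ``ps_constraints``, when given, is (re)attached to the graph first.
    Posteriors at every boundary are normalized joint tables over the
    adjacent segments' configurations.
    """
    if ps_constraints is not None:
        from .genotype_graph import attach_phase_sets
        attach_phase_sets(graph, ps_constraints)
    res = forward(graph, cond, params, cm)
    flat = res.flat
    n_seg = graph.n_segments
    counts = graph.config_counts()
    sizes = [counts[s] * counts[s + 1] for s in range(n_seg - 1)]
    tables_flat = np.zeros(max(sum(sizes), 1))
    marg0 = np.zeros(counts[0])
    _kernels.lsm_backward_kernel(
        flat.seg_off, flat.amb_off, flat.amb_pos, flat.cfg_off,
        flat.cfg_dat_off, flat.cfg_h1, flat.cfg_h2, flat.cfg_w,
        flat.bnd_off, flat.bnd_f, flat.bnd_trivial,
        flat.fixed_mask, flat.fixed_h, res.cond, res.weights,
        emission_prob(0, 0, res.k_total), emission_prob(0, 1, res.k_total),
        res.t_e, res.t_s, res.alpha, res.a_off, tables_flat, marg0)
    tables = []
    off = 0
    for s in range(n_seg - 1):
        tables.append(tables_flat[off:off + sizes[s]].reshape(
            counts[s], counts[s + 1]).copy())
        off += sizes[s]
    res.boundary_posteriors = tables
    res.marg0 = marg0
    return res


def sample_pair(res: LsmResult, rng: np.random.Generator):
    """Stochastic backward traceback; returns (h1, h2, config_path)."""
    n_seg = res.graph.n_segments
    uniforms = rng.random(3 * n_seg)
    cfg_path = np.empty(n_seg, np.int32)
    _kernels.lsm_sample_kernel(
        res.flat.cfg_off, res.flat.bnd_off, res.flat.bnd_f,
        res.flat.bnd_trivial, res.weights, res.t_e, res.t_s,
        res.alpha, res.a_off, uniforms, cfg_path)
    h1, h2 = res.graph.pair_from_configs(cfg_path)
    return h1, h2, cfg_path


def accumulate_and_solve(graph: GenotypeGraph):
    """Best path through the posteriors averaged over main iterations.

    Boundary tables are averaged arithmetically, converted to row-normalized
    transition probabilities, and the maximum-product configuration path is
    found by dynamic programming.  Deterministic given the stored tables.
    Returns (h1, h2, config_path).
    """
    marg0, tables = graph.averaged_posteriors()
    n_seg = graph.n_segments
    counts = graph.config_counts()
    logs = [np.full(c, -np.inf) for c in counts]
    back = [np.zeros(c, dtype=np.int64) for c in counts]
    with np.errstate(divide="ignore"):
        logs[0] = np.log(np.maximum(marg0, 1e-300))
        for s in range(n_seg - 1):
            t = tables[s]
            rows = t.sum(axis=1, keepdims=True)
            cond = np.log(np.maximum(t / np.maximum(rows, 1e-300), 1e-300))
            score = logs[s][:, None] + cond
            back[s + 1] = np.argmax(score, axis=0)
            logs[s + 1] = np.max(score, axis=0)
    cfg_path = np.empty(n_seg, np.int64)
    cfg_path[-1] = int(np.argmax(logs[-1]))
    for s in range(n_seg - 2, -1, -1):
        cfg_path[s] = back[s + 1][cfg_path[s + 1]]
    h1, h2 = graph.pair_from_configs(cfg_path)
    return h1, h2, cfg_path
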