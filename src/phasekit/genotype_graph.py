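"""Compact segmented representation of the haplotype pairs consistent with
one individual's genotypes over a window.

Segments initially hold at most three heterozygous genotypes; each segment
stores the admissible local configurations (alleles of both haplotypes at
the ambiguous sites).  Scaffold constraints prune configurations; phase-set
constraints weight them; pruning iterations merge adjacent segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import NamedTuple, Optional

import numpy as np

from .io_formats import DataInconsistencyError

DEFAULT_EPS = 1e-4
MAX_ENUM_PATHS = 1 << 16


@dataclass
class PhaseSetConstraints:
    """Phase sets for one individual: variant index -> (ps_id, h1 allele).

    ``eps`` is the assumed error rate of the read-backed phase information;
    consistency of a haplotype pair is evaluated on the relative orientation
    of consecutive hets only, so the per-set global flip is immaterial.
    """

    entries: dict
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if not 0.0 < self.eps < 0.5 + 1e-12:
            raise ValueError("eps must lie in (0, 0.5]")


class FlatGraph(NamedTuple):
    """Array view of a graph consumed by the numba HMM kernels."""

    seg_off: np.ndarray
    amb_off: np.ndarray
    amb_pos: np.ndarray
    cfg_off: np.ndarray
    cfg_dat_off: np.ndarray
    cfg_h1: np.ndarray
    cfg_h2: np.ndarray
    cfg_w: np.ndarray
    bnd_off: np.ndarray
    bnd_f: np.ndarray
    bnd_trivial: np.ndarray
    fixed_mask: np.ndarray
    fixed_h: np.ndarray


class GenotypeGraph:
    """Per-individual, per-window genotype graph."""

    def __init__(self, g_row, seg_starts, amb_sites, cfg_h1, cfg_h2):
        self.g = np.asarray(g_row, dtype=np.int8)
        self.seg_starts = list(seg_starts)           # len n_seg + 1
        self.amb_sites = [np.asarray(a, dtype=np.int32) for a in amb_sites]
        self.cfg_h1 = [np.asarray(c, dtype=np.uint8) for c in cfg_h1]
        self.cfg_h2 = [np.asarray(c, dtype=np.uint8) for c in cfg_h2]
        self.log_w = [np.zeros(c.shape[0]) for c in self.cfg_h1]
        self.bnd_logf: list = [None] * (self.n_segments - 1)
        self.ps: Optional[PhaseSetConstraints] = None
        self._flat: Optional[FlatGraph] = None
        # accumulated main-iteration posteriors
        self._acc_marg0: Optional[np.ndarray] = None
        self._acc_tables: Optional[list] = None
        self._n_acc = 0

    # -- structure -----------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.seg_starts) - 1

    @property
    def n_sites(self) -> int:
        return self.seg_starts[-1]

    def config_counts(self):
        return [c.shape[0] for c in self.cfg_h1]

    @property
    def n_paths(self) -> int:
        out = 1
        for c in self.config_counts():
            out *= c
        return out

    def het_sites(self) -> np.ndarray:
        return np.flatnonzero(self.g == 1)

    def segment_of(self, site: int) -> int:
        return int(np.searchsorted(self.seg_starts, site, side="right") - 1)

    # -- flattening for the kernels ------------------------------------

    def _invalidate(self):
        self._flat = None

    def flatten(self) -> FlatGraph:
        if self._flat is not None:
            return self._flat
        n_seg = self.n_segments
        seg_off = np.asarray(self.seg_starts, dtype=np.int32)
        amb_off = np.zeros(n_seg + 1, np.int32)
        cfg_off = np.zeros(n_seg + 1, np.int32)
        cfg_dat_off = np.zeros(n_seg, np.int32)
        tot = 0
        for s in range(n_seg):
            amb_off[s + 1] = amb_off[s] + len(self.amb_sites[s])
            cfg_off[s + 1] = cfg_off[s] + self.cfg_h1[s].shape[0]
            cfg_dat_off[s] = tot
            tot += self.cfg_h1[s].size
        amb_pos = (np.concatenate(self.amb_sites)
                   if amb_off[-1] else np.empty(0, np.int32)).astype(np.int32)
        cfg_h1 = np.concatenate([c.ravel() for c in self.cfg_h1]).astype(np.uint8)
        cfg_h2 = np.concatenate([c.ravel() for c in self.cfg_h2]).astype(np.uint8)
        cfg_w = np.concatenate([np.exp(w - w.max()) for w in self.log_w])
        bnd_off = np.zeros(max(n_seg - 1, 1), np.int64)
        sizes = [self.cfg_h1[s].shape[0] * self.cfg_h1[s + 1].shape[0]
                 for s in range(n_seg - 1)]
        btot = 0
        for s in range(n_seg - 1):
            bnd_off[s] = btot
            btot += sizes[s]
        bnd_f = np.ones(max(btot, 1), np.float64)
        bnd_trivial = np.ones(max(n_seg - 1, 1), np.bool_)
        for s in range(n_seg - 1):
            lf = self.bnd_logf[s]
            if lf is not None:
                bnd_f[bnd_off[s]:bnd_off[s] + sizes[s]] = np.exp(
                    lf - lf.max()).ravel()
                bnd_trivial[s] = False
        fixed_mask = np.ones(self.n_sites, np.bool_)
        fixed_h = np.zeros(self.n_sites, np.uint8)
        hom = self.g >= 0
        fixed_h[hom] = (self.g[hom] // 2).astype(np.uint8)
        for a in self.amb_sites:
            fixed_mask[a] = False
        self._flat = FlatGraph(seg_off, amb_off, amb_pos, cfg_off, cfg_dat_off,
                               cfg_h1, cfg_h2, cfg_w, bnd_off, bnd_f,
                               bnd_trivial, fixed_mask, fixed_h)
        return self._flat

    # -- path reconstruction -------------------------------------------

    def pair_from_configs(self, cfg_path):
        """Haplotype pair (h1, h2) realized by one configuration per segment."""
        h1 = np.zeros(self.n_sites, np.uint8)
        h2 = np.zeros(self.n_sites, np.uint8)
        hom = self.g >= 0
        h1[hom] = h2[hom] = (self.g[hom] // 2).astype(np.uint8)
        for s, c in enumerate(cfg_path):
            amb = self.amb_sites[s]
            h1[amb] = self.cfg_h1[s][c]
            h2[amb] = self.cfg_h2[s][c]
        return h1, h2

    # -- stored posteriors (main iterations) ---------------------------

    def store_posteriors(self, marg0, tables):
        if self._acc_marg0 is None:
            self._acc_marg0 = np.array(marg0, dtype=np.float64)
            self._acc_tables = [np.array(t, dtype=np.float64) for t in tables]
        else:
            self._acc_marg0 += marg0
            for acc, t in zip(self._acc_tables, tables):
                acc += t
        self._n_acc += 1

    def averaged_posteriors(self):
        if self._n_acc == 0:
            raise ValueError("no stored main-iteration posteriors")
        return (self._acc_marg0 / self._n_acc,
                [t / self._n_acc for t in self._acc_tables])

    def clear_posteriors(self):
        self._acc_marg0 = None
        self._acc_tables = None
        self._n_acc = 0


def build_graph(g_row, b_per_segment: int = 3) -> GenotypeGraph:
    """Group consecutive ambiguous genotypes into segments.

    Hets count one ambiguity unit, missing genotypes two (four completions);
    a segment closes before the ambiguous site that would push it past
    ``b_per_segment`` units, so initial configuration counts never exceed
    ``2 ** b_per_segment``.  Homozygous sites attach to the enclosing
    segment as fixed alleles.
    """
    g = np.asarray(g_row, dtype=np.int8)
    n_sites = len(g)
    if n_sites == 0:
        raise ValueError("empty window")
    seg_starts = [0]
    units = 0
    for l in range(n_sites):
        c = g[l]
        u = 1 if c == 1 else (2 if c < 0 else 0)
        if u and units and units + u > b_per_segment:
            seg_starts.append(l)
            units = 0
        units += u
    seg_starts.append(n_sites)
    amb_sites, cfg_h1, cfg_h2 = [], [], []
    for s in range(len(seg_starts) - 1):
        amb = [l for l in range(seg_starts[s], seg_starts[s + 1])
               if g[l] == 1 or g[l] < 0]
        options = []
        for l in amb:
            if g[l] == 1:
                options.append(((0, 1), (1, 0)))
            else:
                options.append(((0, 0), (0, 1), (1, 0), (1, 1)))
        combos = list(product(*options)) if amb else [()]
        h1 = np.array([[p[0] for p in combo] for combo in combos],
                      dtype=np.uint8).reshape(len(combos), len(amb))
        h2 = np.array([[p[1] for p in combo] for combo in combos],
                      dtype=np.uint8).reshape(len(combos), len(amb))
        amb_sites.append(np.asarray(amb, dtype=np.int32))
        cfg_h1.append(h1)
        cfg_h2.append(h2)
    return GenotypeGraph(g, seg_starts, amb_sites, cfg_h1, cfg_h2)


def enumerate_paths(graph: GenotypeGraph):
    """All haplotype pairs encoded by the graph (small graphs only)."""
    if graph.n_paths > MAX_ENUM_PATHS:
        raise ValueError(f"too many paths to enumerate ({graph.n_paths})")
    out = []
    for cfg_path in product(*(range(c) for c in graph.config_counts())):
        out.append(graph.pair_from_configs(cfg_path))
    return out


def apply_scaffold(graph: GenotypeGraph, scaffold_entries: dict) -> GenotypeGraph:
    """Prune configurations contradicting scaffold alleles (in place).

    ``scaffold_entries`` maps window-local het variant index -> allele of
    the first haplotype.  A segment left without configurations raises
    :class:`DataInconsistencyError` naming the offending variant.
    """
    by_seg: dict = {}
    for site, allele in scaffold_entries.items():
        by_seg.setdefault(graph.segment_of(site), []).append((site, allele))
    for s, pairs in by_seg.items():
        amb = graph.amb_sites[s]
        keep = np.ones(graph.cfg_h1[s].shape[0], dtype=bool)
        for site, allele in pairs:
            slots = np.flatnonzero(amb == site)
            if slots.size == 0:
                continue  # hom site: nothing to constrain
            keep &= graph.cfg_h1[s][:, slots[0]] == allele
        if not keep.any():
            site = pairs[0][0]
            raise DataInconsistencyError(
                f"scaffold inconsistent with genotypes near variant index {site}"
            )
        graph.cfg_h1[s] = graph.cfg_h1[s][keep]
        graph.cfg_h2[s] = graph.cfg_h2[s][keep]
        graph.log_w[s] = graph.log_w[s][keep]
        for b in (s - 1, s):
            if 0 <= b < graph.n_segments - 1 and graph.bnd_logf[b] is not None:
                if b == s - 1:
                    graph.bnd_logf[b] = graph.bnd_logf[b][:, keep]
                else:
                    graph.bnd_logf[b] = graph.bnd_logf[b][keep, :]
    graph._invalidate()
    return graph


def attach_phase_sets(graph: GenotypeGraph,
                      constraints: Optional[PhaseSetConstraints]) -> GenotypeGraph:
    """(Re)compute phase-set weights for the current segmentation.

    Each ordered pair of consecutive hets in the same phase set contributes
    log(1 - eps) when a configuration's relative orientation agrees with the
    phase set and log(eps) otherwise; pairs within one segment weight its
    configurations, pairs across adjacent segments weight the boundary, and
    pairs spanning non-adjacent segments are unusable until segments merge.
    """
    graph.ps = constraints
    graph.log_w = [np.zeros(c.shape[0]) for c in graph.cfg_h1]
    graph.bnd_logf = [None] * (graph.n_segments - 1)
    graph._invalidate()
    if constraints is None or not constraints.entries:
        return graph
    eps = constraints.eps
    lg_ok, lg_bad = math.log1p(-eps), math.log(eps)
    for u, v in _ps_pairs(graph, constraints):
        eu = constraints.entries[u]
        ev = constraints.entries[v]
        su, sv = graph.segment_of(u), graph.segment_of(v)
        if sv - su > 1:
            continue  # unusable until segments merge
        same_target = eu[1] == ev[1]
        if su == sv:
            amb = graph.amb_sites[su]
            iu = int(np.flatnonzero(amb == u)[0])
            iv = int(np.flatnonzero(amb == v)[0])
            agree = (graph.cfg_h1[su][:, iu] == graph.cfg_h1[su][:, iv]) == same_target
            graph.log_w[su] = graph.log_w[su] + np.where(agree, lg_ok, lg_bad)
        elif sv == su + 1:
            iu = int(np.flatnonzero(graph.amb_sites[su] == u)[0])
            iv = int(np.flatnonzero(graph.amb_sites[sv] == v)[0])
            au = graph.cfg_h1[su][:, iu][:, None]
            av = graph.cfg_h1[sv][:, iv][None, :]
            agree = (au == av) == same_target
            lf = np.where(agree, lg_ok, lg_bad)
            if graph.bnd_logf[su] is None:
                graph.bnd_logf[su] = lf.astype(np.float64)
            else:
                graph.bnd_logf[su] = graph.bnd_logf[su] + lf
    return graph


def _ps_pairs(graph: GenotypeGraph, constraints: PhaseSetConstraints):
    """Consecutive het pairs within each phase set (in site order)."""
    by_set: dict = {}
    het = set(int(h) for h in graph.het_sites())
    for site in sorted(constraints.entries):
        if site in het:
            by_set.setdefault(constraints.entries[site][0], []).append(site)
    for sites in by_set.values():
        yield from zip(sites[:-1], sites[1:])


def phase_set_log_weight(pair, constraints: PhaseSetConstraints,
                         graph: GenotypeGraph) -> float:
    """Phase-set log-probability of one haplotype pair under the graph.

    Only pairs of consecutive hets lying in the same or adjacent segments
    are usable; others contribute zero.
    """
    h1 = np.asarray(pair[0])
    eps = constraints.eps
    lg_ok, lg_bad = math.log1p(-eps), math.log(eps)
    out = 0.0
    for u, v in _ps_pairs(graph, constraints):
        eu = constraints.entries[u]
        ev = constraints.entries[v]
        if graph.segment_of(v) - graph.segment_of(u) > 1:
            continue
        agree = (h1[u] == h1[v]) == (eu[1] == ev[1])
        out += lg_ok if agree else lg_bad
    return out


def merge_segments(graph: GenotypeGraph, posteriors,
                   keep_threshold: float = 1e-3) -> GenotypeGraph:
    """Merge disjoint adjacent segment pairs, trimming unlikely combinations.

    ``posteriors`` holds one normalized [C_s, C_{s+1}] joint table per
    boundary (from the latest forward-backward pass).  In each merged
    segment only combinations with posterior >= keep_threshold survive; the
    top combination always survives.  The path count never increases.
    Stored main-iteration posteriors are cleared (shapes change).
    """
    n_seg = graph.n_segments
    if n_seg < 2:
        return graph
    new_starts = [0]
    new_amb, new_h1, new_h2 = [], [], []
    s = 0
    while s < n_seg:
        if s + 1 < n_seg:
            t = posteriors[s]
            keep = np.asarray(t) >= keep_threshold
            keep[np.unravel_index(np.argmax(t), np.shape(t))] = True
            ii, jj = np.nonzero(keep)
            amb = np.concatenate([graph.amb_sites[s], graph.amb_sites[s + 1]])
            h1 = np.hstack([graph.cfg_h1[s][ii], graph.cfg_h1[s + 1][jj]])
            h2 = np.hstack([graph.cfg_h2[s][ii], graph.cfg_h2[s + 1][jj]])
            new_starts.append(graph.seg_starts[s + 2])
            new_amb.append(amb)
            new_h1.append(h1)
            new_h2.append(h2)
            s += 2
        else:
            new_starts.append(graph.seg_starts[s + 1])
            new_amb.append(graph.amb_sites[s])
            new_h1.append(graph.cfg_h1[s])
            new_h2.append(graph.cfg_h2[s])
            s += 1
    out = GenotypeGraph(graph.g, new_starts, new_amb, new_h1, new_h2)
    attach_phase_sets(out, graph.ps)
    return out
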