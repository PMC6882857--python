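"""Run orchestration: windows, the MCMC schedule, per-individual updates,
reference panels, IBD2 exclusions and window ligation."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import lsm
from .genotype_graph import (
    GenotypeGraph,
    PhaseSetConstraints,
    attach_phase_sets,
    build_graph,
    apply_scaffold,
    merge_segments,
)
from .io_formats import GenotypeMatrix, VariantTable
from .pbwt import (
    pbwt_build,
    pbwt_init_phase,
    pbwt_long_genotype_matches,
    select_conditioning_set,
)

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = "5b,1p,1b,1p,1b,1p,5m"


def parse_schedule(spec: str) -> list:
    """'5b,1p,...' -> per-iteration type list over {'b', 'p', 'm'}."""
    out = []
    for tok in spec.replace(" ", "").split(","):
        if not tok:
            continue
        kind = tok[-1]
        if kind not in "bpm":
            raise ValueError(f"bad iteration token {tok!r}")
        count = int(tok[:-1]) if tok[:-1] else 1
        out.extend(kind * count)
    if not out:
        raise ValueError("empty iteration schedule")
    return out


@dataclass
class RunConfig:
    """Phasing-run parameters (defaults: 15 iterations, 3 pruning stages)."""

    p_neighbors: int = 4          # PBWT neighbours per stored site (P)
    stride: int = 8               # PBWT storage stride (S)
    window_bp: int = 2_000_000    # sliding window size (W)
    overlap_bp: int = 250_000
    schedule: str = DEFAULT_SCHEDULE
    eps_ps: float = 1e-4          # phase-set error rate
    ne: float = lsm.DEFAULT_NE
    seed: int = 0
    b_per_segment: int = 3
    prune_keep: float = 1e-3
    ibd2_protection: bool = True
    max_k: int = 64               # LSM state cap (selection K is unlimited)

    def __post_init__(self):
        if not self.window_bp > self.overlap_bp >= 0:
            raise ValueError("need window_bp > overlap_bp >= 0")
        self.iterations = parse_schedule(self.schedule)


class Window(NamedTuple):
    start_bp: int
    end_bp: int     # half-open
    lo_idx: int
    hi_idx: int     # half-open variant-index span


def make_windows(vt: VariantTable, window_bp: int, overlap_bp: int) -> list:
    """Half-open bp windows covering every variant.

    A chromosome shorter than the window yields a single window; otherwise
    starts advance by window_bp - overlap_bp.
    """
    if not window_bp > overlap_bp >= 0:
        raise ValueError("need window_bp > overlap_bp >= 0")
    first, last = int(vt.pos[0]), int(vt.pos[-1])
    if last - first + 1 <= window_bp:
        return [Window(first, last + 1, 0, vt.n_sites)]
    out = []
    step = window_bp - overlap_bp
    start = first
    while True:
        end = start + window_bp
        if end >= last + 1:
            end = last + 1
        lo = int(np.searchsorted(vt.pos, start, side="left"))
        hi = int(np.searchsorted(vt.pos, end, side="left"))
        if hi > lo:
            out.append(Window(start, end, lo, hi))
        if end >= last + 1:
            break
        start += step
    return out


@dataclass
class PhasingRun:
    """Mutable state of one phasing run (see :func:`phase`)."""

    gm: GenotypeMatrix
    vt: VariantTable
    config: RunConfig
    windows: list
    H_all: np.ndarray            # [2N (+2R), L]; first 2N rows are updated
    n_main: int                  # N (main-panel individuals)
    graphs: list                 # graphs[i][w]
    ibd2: dict                   # (i, w) -> set of excluded individuals j
    params: lsm.LsmParams
    rng: np.random.Generator
    state: object = None         # current PbwtState
    k_log: list = field(default_factory=list)

    @property
    def H(self) -> np.ndarray:
        return self.H_all[: 2 * self.n_main]


def _window_locals(entries: dict, i: int, win: Window) -> dict:
    """Per-individual constraint entries restricted to a window (local idx)."""
    out = {}
    for (ii, l), v in entries.items():
        if ii == i and win.lo_idx <= l < win.hi_idx:
            out[l - win.lo_idx] = v
    return out


def _gauge_align(h1, h2, cur1, g_row):
    """Swap the pair if the majority of hets disagrees with the current row."""
    hets = np.flatnonzero(g_row == 1)
    if hets.size == 0:
        return h1, h2
    agree = int((h1[hets] == cur1[hets]).sum())
    if 2 * agree < hets.size:
        return h2, h1
    return h1, h2


def update_individual(run: PhasingRun, i: int, w: int, iteration_type: str):
    """Resample individual ``i`` in window ``w``; returns K (or None if
    nothing to sample).

    The conditioning set excludes the individual's own two haplotypes and
    all haplotypes of individuals IBD2 with ``i`` in this window.  Burn-in
    iterations only resample; pruning iterations also merge graph segments;
    main iterations store the boundary posteriors for the final solve.
    """
    win = run.windows[w]
    graph = run.graphs[i][w]
    cfg = run.config
    if graph.n_paths == 1:
        h1, h2 = graph.pair_from_configs([0] * graph.n_segments)
        run.H[2 * i, win.lo_idx:win.hi_idx] = h1
        run.H[2 * i + 1, win.lo_idx:win.hi_idx] = h2
        return None
    exclude = set()
    for j in run.ibd2.get((i, w), ()):
        exclude.add(2 * j)
        exclude.add(2 * j + 1)
    cond_idx = select_conditioning_set(
        run.state, (2 * i, 2 * i + 1), win.lo_idx, win.hi_idx,
        cfg.p_neighbors, exclude, H=run.H_all)
    k_selected = int(len(cond_idx))
    if cfg.max_k and k_selected > cfg.max_k:
        cond_idx = np.sort(run.rng.choice(cond_idx, cfg.max_k, replace=False))
    cond = run.H_all[cond_idx][:, win.lo_idx:win.hi_idx]
    cm = run.vt.cm[win.lo_idx:win.hi_idx]
    if iteration_type == "b":
        res = lsm.forward(graph, cond, run.params, cm)
    else:
        res = lsm.forward_backward(graph, cond, run.params, cm)
    h1, h2, _ = lsm.sample_pair(res, run.rng)
    if iteration_type == "p":
        run.graphs[i][w] = merge_segments(graph, res.boundary_posteriors,
                                          cfg.prune_keep)
    elif iteration_type == "m":
        graph.store_posteriors(res.marg0, res.boundary_posteriors)
    g_row = run.gm.codes[i, win.lo_idx:win.hi_idx]
    cur1 = run.H[2 * i, win.lo_idx:win.hi_idx]
    h1, h2 = _gauge_align(h1, h2, cur1, g_row)
    run.H[2 * i, win.lo_idx:win.hi_idx] = h1
    run.H[2 * i + 1, win.lo_idx:win.hi_idx] = h2
    return k_selected


def ligate_windows(pairs, windows, g_row, locked=None):
    """Stitch per-window haplotype pairs into one chromosome-wide pair.

    The relative orientation of consecutive windows is chosen by majority
    vote over the shared hets of the overlap (ties keep the current
    orientation); the second half of each overlap comes from the later
    window.  ``locked`` windows (scaffold-constrained) are never flipped:
    the scaffold orientation has priority over the vote.  ``pairs`` may
    carry extra aligned arrays (certainties) as a third element; they are
    stitched with the same cuts.
    """
    L = len(g_row)
    h1 = np.zeros(L, np.uint8)
    h2 = np.zeros(L, np.uint8)
    extra = np.ones(L, np.float64)
    has_extra = len(pairs[0]) > 2
    win0 = windows[0]
    h1[win0.lo_idx:win0.hi_idx] = pairs[0][0]
    h2[win0.lo_idx:win0.hi_idx] = pairs[0][1]
    if has_extra:
        extra[win0.lo_idx:win0.hi_idx] = pairs[0][2]
    written_hi = win0.hi_idx
    for w in range(1, len(windows)):
        win = windows[w]
        p1, p2 = pairs[w][0], pairs[w][1]
        ov = np.arange(win.lo_idx, min(written_hi, win.hi_idx))
        ov_hets = ov[g_row[ov] == 1]
        if ov_hets.size == 0:
            logger.warning("no shared hets in overlap before window %d", w)
        elif locked is None or not locked[w]:
            agree = int((p1[ov_hets - win.lo_idx] == h1[ov_hets]).sum())
            if 2 * agree < ov_hets.size:
                p1, p2 = p2, p1
        mid = (win.lo_idx + min(written_hi, win.hi_idx)) // 2
        h1[mid:win.hi_idx] = p1[mid - win.lo_idx:]
        h2[mid:win.hi_idx] = p2[mid - win.lo_idx:]
        if has_extra:
            extra[mid:win.hi_idx] = pairs[w][2][mid - win.lo_idx:]
        written_hi = win.hi_idx
    if has_extra:
        return h1, h2, extra
    return h1, h2


def _window_certainty(graph: GenotypeGraph, cfg_path) -> np.ndarray:
    """Per-site certainty of the solved path from the averaged posteriors."""
    out = np.ones(graph.n_sites, np.float64)
    if graph._n_acc == 0:
        return out
    marg0, tables = graph.averaged_posteriors()
    for s in range(graph.n_segments):
        if s == 0:
            tot = marg0.sum()
            p = marg0[cfg_path[0]] / tot if tot > 0 else 1.0
        else:
            row = tables[s - 1][cfg_path[s - 1]]
            tot = row.sum()
            p = row[cfg_path[s]] / tot if tot > 0 else 1.0
        out[graph.amb_sites[s]] = p
    return out


@dataclass
class PhasingResult:
    haplotypes: np.ndarray       # uint8 [2N, L]
    certainty: np.ndarray        # float64 [N, L]
    diagnostics: dict


def phase(gm: GenotypeMatrix, vt: VariantTable, config: RunConfig,
          reference: Optional[np.ndarray] = None,
          scaffold: Optional[dict] = None,
          phase_sets: Optional[dict] = None) -> PhasingResult:
    """Phase a genotype panel; fully deterministic given the config seed.

    ``reference``: phased haplotypes (2R x L, aligned to ``vt``) appended to
    the PBWT but never updated.  ``scaffold``: (individual, site) -> allele
    hard constraints.  ``phase_sets``: (individual, site) -> (ps_id, allele)
    probabilistic constraints with error rate ``config.eps_ps``.
    """
    codes = gm.codes
    N, L = codes.shape
    if L != vt.n_sites:
        raise ValueError("genotypes and variant table disagree on L")
    windows = make_windows(vt, config.window_bp, config.overlap_bp)
    rng = np.random.default_rng(config.seed)

    H_init = pbwt_init_phase(gm, vt, config.seed)
    n_ref = 0 if reference is None else reference.shape[0]
    H_all = np.empty((2 * N + n_ref, L), np.uint8)
    H_all[: 2 * N] = H_init
    if reference is not None:
        H_all[2 * N:] = reference

    ibd2: dict = {}
    if config.ibd2_protection and N > 2:
        span = int(vt.pos[-1] - vt.pos[0] + 1)
        min_span = min(config.window_bp, span)
        for c in pbwt_long_genotype_matches(gm, vt, windows, min_span):
            ibd2.setdefault((c.i, c.w), set()).add(c.j)
            ibd2.setdefault((c.j, c.w), set()).add(c.i)
        if ibd2:
            logger.info("IBD2 protection: %d (individual, window) exclusions",
                        len(ibd2))

    graphs = []
    for i in range(N):
        row = []
        for win in windows:
            graph = build_graph(codes[i, win.lo_idx:win.hi_idx],
                                config.b_per_segment)
            if scaffold:
                entries = _window_locals(scaffold, i, win)
                if entries:
                    apply_scaffold(graph, entries)
            if phase_sets:
                local = _window_locals(phase_sets, i, win)
                attach_phase_sets(graph, PhaseSetConstraints(
                    entries=local, eps=config.eps_ps))
            row.append(graph)
        graphs.append(row)

    params = lsm.LsmParams(ne=config.ne, n_hap=2 * N + n_ref)
    run = PhasingRun(gm=gm, vt=vt, config=config, windows=windows,
                     H_all=H_all, n_main=N, graphs=graphs, ibd2=ibd2,
                     params=params, rng=rng)
    extra_sites = sorted({win.hi_idx - 1 for win in windows})

    mean_k = []
    for it, it_type in enumerate(config.iterations):
        t0 = time.perf_counter()
        run.state = pbwt_build(H_all, config.stride, extra_sites)
        k_sum, k_n = 0, 0
        for i in rng.permutation(N):
            for w in range(len(windows)):
                k = update_individual(run, int(i), w, it_type)
                if k is not None:
                    k_sum += k
                    k_n += 1
        mean_k.append(k_sum / max(k_n, 1))
        logger.info("iteration %d (%s): mean K = %.1f, %.2fs",
                    it + 1, it_type, mean_k[-1], time.perf_counter() - t0)

    # final solve from averaged main-iteration posteriors, then ligation
    haps = np.empty((2 * N, L), np.uint8)
    certainty = np.ones((N, L), np.float64)
    for i in range(N):
        solved = []
        for w, win in enumerate(windows):
            graph = run.graphs[i][w]
            if graph._n_acc > 0:
                h1, h2, cfg_path = lsm.accumulate_and_solve(graph)
                pp = _window_certainty(graph, cfg_path)
            else:
                # trivial graph (single path) or schedule without main
                # iterations: fall back to the current estimate
                h1 = run.H[2 * i, win.lo_idx:win.hi_idx].copy()
                h2 = run.H[2 * i + 1, win.lo_idx:win.hi_idx].copy()
                pp = np.ones(win.hi_idx - win.lo_idx)
            solved.append((h1, h2, pp))
        locked = None
        if scaffold:
            locked = [
                any((i, l) in scaffold for l in range(win.lo_idx, win.hi_idx))
                for win in windows
            ]
        h1, h2, pp = ligate_windows(solved, windows, codes[i], locked)
        haps[2 * i] = h1
        haps[2 * i + 1] = h2
        certainty[i] = pp
    return PhasingResult(
        haplotypes=haps,
        certainty=certainty,
        diagnostics={
            "mean_k": mean_k,
            "iterations": list(config.iterations),
            "n_windows": len(windows),
            "n_ibd2_exclusions": len(ibd2),
        },
    )
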