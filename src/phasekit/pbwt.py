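"""Positional Burrows-Wheeler transform machinery.

Construction of prefix/divergence/locator arrays at a variant stride,
neighbour queries used to select conditioning haplotypes, long genotype
matches for IBD2 protection, and the PBWT-guided haplotype initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _kernels
from .io_formats import GenotypeMatrix, VariantTable

DEFAULT_STRIDE = 8


class Ibd2Constraint(NamedTuple):
    """Two individuals sharing both haplotypes over a whole window."""

    i: int
    j: int
    w: int


@dataclass
class PbwtState:
    """Prefix (A), divergence (Dv) and locator (I) arrays at stored sites.

    Arrays at stored site ``l`` order the haplotypes by reversed prefix over
    sites ``[0, l]``; ``Dv[r]`` is the first site of the match between the
    haplotypes at ranks ``r`` and ``r - 1`` (``Dv[0] == l + 1``);
    ``I`` is the inverse permutation of ``A``.
    """

    stride: int
    sites: np.ndarray            # stored site indices, sorted
    A: np.ndarray                # int32 [n_stored, M]
    Dv: np.ndarray               # int32 [n_stored, M]
    I: np.ndarray                # int32 [n_stored, M]
    n_haplotypes: int
    _slot: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._slot = {int(s): i for i, s in enumerate(self.sites)}

    def slot_of(self, l: int) -> int:
        try:
            return self._slot[int(l)]
        except KeyError:
            raise ValueError(f"site {l} is not a stored PBWT site") from None

    def slots_in(self, lo: int, hi: int) -> np.ndarray:
        """Stored-array slots whose site index lies in [lo, hi)."""
        mask = (self.sites >= lo) & (self.sites < hi)
        return np.flatnonzero(mask).astype(np.int64)


def pbwt_build(H: np.ndarray, stride: int = DEFAULT_STRIDE,
               extra_sites=None) -> PbwtState:
    """Single left-to-right sweep building the PBWT of binary haplotypes.

    Arrays are retained at sites ``l % stride == 0``, at the last site, and
    at any ``extra_sites`` requested by the caller (window ends).
    """
    H = np.ascontiguousarray(H, dtype=np.uint8)
    if H.size and H.max() > 1:
        raise ValueError("haplotype matrix has non-binary entries")
    M, L = H.shape
    stored = set(range(0, L, stride))
    stored.add(L - 1)
    if extra_sites is not None:
        stored.update(int(s) for s in extra_sites)
    sites = np.asarray(sorted(s for s in stored if 0 <= s < L), dtype=np.int64)
    A, Dv, I = _kernels.pbwt_build_kernel(H, sites)
    return PbwtState(stride=stride, sites=sites, A=A, Dv=Dv, I=I,
                     n_haplotypes=M)


def pbwt_neighbors(state: PbwtState, hap: int, l: int, P: int,
                   exclude=frozenset()) -> list:
    """Up to P haplotypes sharing the longest prefixes with ``hap`` at ``l``.

    Greedy walk away from the haplotype's rank in the prefix array, taking
    at each step the side with the longer divergence-backed match; ties go to
    the lower-rank (up) side.  ``exclude`` lists haplotype indices never
    returned (their divergence still truncates matches across them).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    slot = state.slot_of(l)
    M = state.n_haplotypes
    excluded = np.zeros(M, dtype=bool)
    excluded[list(exclude)] = True
    excluded[hap] = True
    A = state.A[slot]
    Dv = state.Dv[slot]
    r = int(state.I[slot, hap])
    out = []
    cu, su, up_rank, up_start = r, 0, -1, 0
    cd, sd, down_rank, down_start = r, 0, -1, 0
    while len(out) < P:
        if up_rank < 0:
            while cu > 0:
                su = max(su, int(Dv[cu]))
                cu -= 1
                if not excluded[A[cu]]:
                    up_rank, up_start = cu, su
                    break
        if down_rank < 0:
            while cd < M - 1:
                cd += 1
                sd = max(sd, int(Dv[cd]))
                if not excluded[A[cd]]:
                    down_rank, down_start = cd, sd
                    break
        if up_rank < 0 and down_rank < 0:
            break
        if down_rank < 0 or (up_rank >= 0 and up_start <= down_start):
            out.append(int(A[up_rank]))
            excluded[A[up_rank]] = True
            up_rank = -1
        else:
            out.append(int(A[down_rank]))
            excluded[A[down_rank]] = True
            down_rank = -1
    return out


def select_conditioning_set(state: PbwtState, d, lo: int, hi: int, P: int,
                            exclude=frozenset(), H=None) -> np.ndarray:
    """Collapse per-stored-site neighbour reports over a window into K ids.

    ``d`` is the pair of target haplotype indices, ``[lo, hi)`` the window's
    variant-index span.  Returns sorted distinct haplotype indices; never
    contains the targets or anything in ``exclude``.  When the haplotype
    matrix ``H`` is given, indices carrying identical sequences over the
    window collapse to one representative (K counts distinct haplotypes).
    """
    h1, h2 = d
    slots = state.slots_in(lo, hi)
    if slots.size == 0:
        raise ValueError(f"no stored PBWT site in window [{lo}, {hi})")
    excluded = np.zeros(state.n_haplotypes, dtype=bool)
    excluded[list(exclude)] = True
    excluded[h1] = True
    excluded[h2] = True
    mask = _kernels.collect_window_kernel(
        state.A, state.Dv, state.I, slots,
        np.int64(h1), np.int64(h2), np.int64(P), excluded)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            "conditioning set empty after exclusions; increase P or sample size"
        )
    if H is not None:
        seen = {}
        for k in idx:
            seen.setdefault(H[k, lo:hi].tobytes(), int(k))
        idx = np.array(sorted(seen.values()), dtype=idx.dtype)
    return idx


def genotype_match_runs(codes: np.ndarray, pos: np.ndarray,
                        min_span_bp: float) -> np.ndarray:
    """Maximal pairwise genotype-equality runs spanning >= min_span_bp.

    MISSING genotypes act as wildcards.  A run over sites ``[a, b]`` spans
    ``pos[b] - pos[a] + 1`` bp.  Returns an int64 array of rows
    ``(i, j, a, b)``.
    """
    codes = np.ascontiguousarray(codes, dtype=np.int8)
    pos = np.ascontiguousarray(pos, dtype=np.int64)
    dummy = np.empty((1, 4), dtype=np.int64)
    n = _kernels.ibd2_scan_kernel(codes, pos, np.int64(min_span_bp), dummy, True)
    out = np.empty((max(n, 1), 4), dtype=np.int64)
    _kernels.ibd2_scan_kernel(codes, pos, np.int64(min_span_bp), out, False)
    return out[:n]


def pbwt_long_genotype_matches(gm: GenotypeMatrix, vt: VariantTable,
                               windows, min_span_bp: float) -> list:
    """IBD2 constraints: windows fully covered by a long genotype match.

    ``windows`` is a sequence with ``lo_idx``/``hi_idx`` variant-index spans
    (see engine.make_windows).  Emits one :class:`Ibd2Constraint` per
    (pair, window) where the match covers every variant of the window.
    """
    runs = genotype_match_runs(gm.codes, vt.pos, min_span_bp)
    out = []
    for i, j, a, b in runs:
        for w, win in enumerate(windows):
            if a <= win.lo_idx and b >= win.hi_idx - 1:
                out.append(Ibd2Constraint(int(i), int(j), w))
    return out


def pbwt_init_phase(gm: GenotypeMatrix, vt: VariantTable,
                    seed: int) -> np.ndarray:
    """PBWT-guided initial phasing sweep (far better than random).

    Builds the per-site allele vector with homozygous alleles fixed and het
    alleles unknown, imputes the unknowns from prefix-array neighbours of
    the previous site, enforces complementarity at hets, and advances the
    PBWT.  Missing genotypes and otherwise-unresolvable alleles draw from
    the site allele frequency.  Deterministic per seed.
    """
    codes = np.ascontiguousarray(gm.codes, dtype=np.int8)
    N, L = codes.shape
    ok = codes >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(ok, codes, 0).sum(axis=0) / np.maximum(
            2 * ok.sum(axis=0), 1)
    freq = np.where(ok.any(axis=0), freq, 0.5)
    rng = np.random.default_rng(seed)
    U = rng.random((2 * N, L))
    return _kernels.init_phase_kernel(codes, freq.astype(np.float64), U)
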