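"""Synthetic data with known truth and the evaluation metrics.

A mosaic population simulator (founder haplotypes recombined into samples),
planted read-backed phase sets and scaffolds, trio Mendel phasing, and the
switch-error metrics used to evaluate phasing accuracy.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GeneticMap, GenotypeMatrix, VariantTable


@dataclass
class TruthSet:
    """Simulated haplotypes plus everything derived from them."""

    chrom: str
    pos: np.ndarray                 # int64 [L]
    haplotypes: np.ndarray          # uint8 [2N, L]
    founders: np.ndarray            # uint8 [F, L]
    founder_of: np.ndarray          # int16 [2N, L]
    sample_ids: list
    trios: list = field(default_factory=list)   # (child, father, mother)

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        h = self.haplotypes.astype(np.int8)
        return (h[0::2] + h[1::2]).astype(np.int8)

    def genotype_matrix(self, phase_sets=None) -> GenotypeMatrix:
        return GenotypeMatrix(codes=self.genotypes(),
                              sample_ids=list(self.sample_ids),
                              phase_sets=dict(phase_sets or {}))

    def variant_table(self, cm_per_mb: float = 1.0) -> VariantTable:
        L = self.n_sites
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos.copy(),
            ids=[f"v{l}" for l in range(L)],
            ref=["A"] * L,
            alt=["G"] * L,
            cm=self.pos.astype(np.float64) * cm_per_mb * 1e-6,
        )

    def pair(self, i: int):
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]


def _mosaic(founders, span, recomb_per_bp, pos, rng):
    """One haplotype copied from founders with Poisson crossovers."""
    F, L = founders.shape
    n_x = rng.poisson(recomb_per_bp * span)
    cuts = np.sort(rng.integers(0, span, size=n_x))
    bounds = np.searchsorted(pos, np.concatenate([cuts, [span + 1]]))
    hap = np.empty(L, np.uint8)
    src = np.empty(L, np.int16)
    start = 0
    for b in bounds:
        f = rng.integers(0, F)
        hap[start:b] = founders[f, start:b]
        src[start:b] = f
        start = b
        if start >= L:
            break
    return hap, src


def simulate_population(n_founders: int, n_samples: int, n_sites: int,
                        span_bp: int = 1_000_000,
                        recomb_per_bp: float = 1e-6,
                        maf_min: float = 0.05,
                        seed: int = 0,
                        chrom: str = "1") -> TruthSet:
    """Founder haplotypes recombined into a mosaic sample panel.

    Founder alleles are i.i.d. Bernoulli with per-site frequency drawn
    uniformly from [maf_min, 1 - maf_min]; every sample haplotype is a
    founder mosaic with Poisson(recomb_per_bp * span_bp) crossovers.
    Deterministic per seed.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(span_bp, size=n_sites, replace=False)) + 1
    freq = rng.uniform(maf_min, 1.0 - maf_min, size=n_sites)
    founders = (rng.random((n_founders, n_sites)) < freq).astype(np.uint8)
    haps = np.empty((2 * n_samples, n_sites), np.uint8)
    src = np.empty((2 * n_samples, n_sites), np.int16)
    for m in range(2 * n_samples):
        haps[m], src[m] = _mosaic(founders, span_bp, recomb_per_bp, pos, rng)
    return TruthSet(chrom=chrom, pos=pos.astype(np.int64), haplotypes=haps,
                    founders=founders, founder_of=src,
                    sample_ids=[f"sample{i}" for i in range(n_samples)])


def add_trio_children(truth: TruthSet, n_trios: int,
                      recomb_per_bp: float = 1e-6, seed: int = 0) -> TruthSet:
    """Append trio children whose gametes recombine the first 2*n_trios samples.

    Parents are taken pairwise ((0,1), (2,3), ...); child i's haplotypes are
    gametes of father 2i and mother 2i+1.  Truth haplotypes of the children
    are exact by construction.
    """
    if 2 * n_trios > truth.n_samples:
        raise ValueError("not enough samples to act as parents")
    rng = np.random.default_rng(seed)
    span = int(truth.pos[-1])
    kids, kid_src, trios = [], [], []
    for t in range(n_trios):
        f, m = 2 * t, 2 * t + 1
        child = truth.n_samples + t
        for parent in (f, m):
            g1, g2 = truth.pair(parent)
            n_x = rng.poisson(recomb_per_bp * span)
            cuts = np.sort(rng.integers(0, span, size=n_x))
            bounds = np.searchsorted(truth.pos, cuts)
            gamete = g1.copy()
            which = rng.integers(0, 2)
            start = 0
            for b in np.concatenate([bounds, [truth.n_sites]]):
                gamete[start:b] = (g1 if which == 0 else g2)[start:b]
                which = 1 - which
                start = b
            kids.append(gamete)
            kid_src.append(np.full(truth.n_sites, -1, np.int16))
        trios.append((child, f, m))
    return TruthSet(
        chrom=truth.chrom, pos=truth.pos,
        haplotypes=np.vstack([truth.haplotypes] + [k[None] for k in kids]),
        founders=truth.founders,
        founder_of=np.vstack([truth.founder_of] + [s[None] for s in kid_src]),
        sample_ids=truth.sample_ids
        + [f"child{t}" for t in range(n_trios)],
        trios=trios,
    )


def simulate_phase_sets(truth: TruthSet, mean_set_len_hets: float = 10.0,
                        flip_error_rate: float = 0.0,
                        coverage_fraction: float = 1.0,
                        seed: int = 0) -> dict:
    """Planted read-backed phase sets: (individual, site) -> (ps_id, allele).

    Consecutive hets are grouped into sets of geometric length, each kept
    with probability coverage_fraction; within-set first-haplotype alleles
    are copied from truth (under a random per-set gauge flip) and then
    flipped independently at flip_error_rate.
    """
    if not (0.0 <= flip_error_rate <= 1.0 and 0.0 <= coverage_fraction <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = truth.genotypes()
    out = {}
    ps_id = 1
    for i in range(truth.n_samples):
        hets = np.flatnonzero(codes[i] == 1)
        t = 0
        while t < len(hets):
            n = max(2, rng.geometric(1.0 / max(mean_set_len_hets, 2.0)))
            group = hets[t:t + n]
            t += n
            if len(group) < 2 or rng.random() >= coverage_fraction:
                continue
            gauge = rng.integers(0, 2)
            for l in group:
                allele = int(truth.haplotypes[2 * i, l]) ^ gauge
                if flip_error_rate and rng.random() < flip_error_rate:
                    allele ^= 1
                out[(i, int(l))] = (ps_id, allele)
            ps_id += 1
    return out


def simulate_scaffold(truth: TruthSet, coverage_fraction: float = 1.0,
                      error_rate: float = 0.0, seed: int = 0) -> dict:
    """Planted scaffold: (individual, site) -> first-haplotype allele."""
    rng = np.random.default_rng(seed)
    codes = truth.genotypes()
    out = {}
    for i in range(truth.n_samples):
        for l in np.flatnonzero(codes[i] == 1):
            if rng.random() < coverage_fraction:
                allele = int(truth.haplotypes[2 * i, l])
                if error_rate and rng.random() < error_rate:
                    allele ^= 1
                out[(i, int(l))] = allele
    return out


def trio_phase(child, father, mother) -> dict:
    """Mendel phasing of child hets: site -> (paternal, maternal) alleles.

    Triple-het sites and Mendel-inconsistent sites are excluded.
    """
    child = np.asarray(child)
    father = np.asarray(father)
    mother = np.asarray(mother)
    out = {}
    for l in np.flatnonzero(child == 1):
        f, m = int(father[l]), int(mother[l])
        if f == MISSING or m == MISSING:
            continue
        if f == 1 and m == 1:
            continue  # triple het
        # transmitted alleles consistent with each parent's genotype
        pf = {0: (0,), 1: (0, 1), 2: (1,)}[f]
        pm = {0: (0,), 1: (0, 1), 2: (1,)}[m]
        solutions = [(a, b) for a in pf for b in pm if a + b == 1]
        if len(solutions) == 1:
            out[int(l)] = solutions[0]
    return out


def switch_error_rate(estimate, truth, eval_sites=None) -> float:
    """Fraction of consecutive het pairs with discordant relative phase.

    Invariant to a global swap of either pair's haplotypes.  ``eval_sites``
    defaults to all sites het in the truth pair.
    """
    e1 = np.asarray(estimate[0])
    t1, t2 = np.asarray(truth[0]), np.asarray(truth[1])
    if eval_sites is None:
        eval_sites = np.flatnonzero(t1 != t2)
    eval_sites = np.asarray(eval_sites)
    if len(eval_sites) < 2:
        raise ValueError("need at least two evaluation hets")
    agree = e1[eval_sites] == t1[eval_sites]
    return float(np.mean(agree[:-1] != agree[1:]))


def switch_vector(estimate, truth, eval_sites) -> np.ndarray:
    """Boolean switch indicator per consecutive eval-het pair."""
    e1 = np.asarray(estimate[0])
    t1 = np.asarray(truth[0])
    agree = e1[eval_sites] == t1[eval_sites]
    return agree[:-1] != agree[1:]


def mean_error_free_length(estimate, truth, positions, eval_sites=None) -> float:
    """Mean bp length of segments free of switch errors.

    Segment boundaries sit halfway between the hets of each switched pair;
    with no switches the whole evaluated span is returned.
    """
    positions = np.asarray(positions)
    t1, t2 = np.asarray(truth[0]), np.asarray(truth[1])
    if eval_sites is None:
        eval_sites = np.flatnonzero(t1 != t2)
    eval_sites = np.asarray(eval_sites)
    if len(eval_sites) < 2:
        raise ValueError("need at least two evaluation hets")
    sw = switch_vector(estimate, truth, eval_sites)
    p = positions[eval_sites]
    cuts = (p[:-1][sw] + p[1:][sw]) / 2.0
    bounds = np.concatenate([[p[0]], cuts, [p[-1]]])
    return float(np.mean(np.diff(bounds)))


# ---------------------------------------------------------------------------
# VCF / map fixture writers (plain text; round-trip through io_formats)
# ---------------------------------------------------------------------------


def write_truth_vcf(path, truth: TruthSet, phase_sets=None,
                    phased: bool = False, missing_mask=None) -> None:
    """Write the truth panel as a VCF of (by default unphased) genotypes.

    ``phase_sets`` annotates covered hets with phased GT + PS; ``phased``
    writes every genotype phased with the truth orientation (reference-panel
    style).  ``missing_mask`` (N x L bool) replaces genotypes with ``./.``.
    """
    codes = truth.genotypes()
    n, L = codes.shape
    fmt = "GT" if phase_sets is None else "GT:PS"
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if phase_sets is not None:
            fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,'
                     'Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.sample_ids) + "\n")
        for l in range(L):
            cols = [truth.chrom, str(int(truth.pos[l])), f"v{l}", "A", "G",
                    ".", "PASS", ".", fmt]
            for i in range(n):
                if missing_mask is not None and missing_mask[i, l]:
                    gt = "./."
                elif phased:
                    gt = f"{truth.haplotypes[2 * i, l]}|{truth.haplotypes[2 * i + 1, l]}"
                else:
                    c = codes[i, l]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(c)]
                if phase_sets is not None:
                    e = phase_sets.get((i, l))
                    if e is not None:
                        gt = f"{e[1]}|{1 - e[1]}:{e[0]}"
                    else:
                        gt += ":."
                cols.append(gt)
            fh.write("\t".join(cols) + "\n")


def write_scaffold_vcf(path, truth: TruthSet, scaffold: dict) -> None:
    """Write a sparse scaffold VCF: phased GT at covered entries only."""
    codes = truth.genotypes()
    covered_sites = sorted({l for (_, l) in scaffold})
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.sample_ids) + "\n")
        for l in covered_sites:
            cols = [truth.chrom, str(int(truth.pos[l])), f"v{l}", "A", "G",
                    ".", "PASS", ".", "GT"]
            for i in range(truth.n_samples):
                e = scaffold.get((i, l))
                if e is not None:
                    cols.append(f"{e}|{1 - e}")
                else:
                    c = int(codes[i, l])
                    cols.append({0: "0/0", 1: "0/1", 2: "1/1"}[c])
            fh.write("\t".join(cols) + "\n")


def write_genetic_map(path, span_bp: int, cm_per_mb: float = 1.0) -> None:
    """Write a 3-column (pos, rate, cM) constant-rate genetic map."""
    with open(path, "wt") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for p in (1, span_bp):
            fh.write(f"{p} {cm_per_mb} {p * cm_per_mb * 1e-6:.6f}\n")


def make_genetic_map(span_bp: int, cm_per_mb: float = 1.0) -> GeneticMap:
    pos = np.array([1, span_bp], dtype=np.int64)
    return GeneticMap(pos=pos, cm=pos * cm_per_mb * 1e-6)
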