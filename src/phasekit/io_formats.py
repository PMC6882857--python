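"""Reading and writing of the standard formats the phaser touches.

Plain or gzipped VCF 4.x (``GT`` and ``PS`` FORMAT fields), HapMap-style
genetic map text, plus the dataset QC and panel-intersection steps applied
before phasing.  Binary BCF is intentionally unsupported.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Genotype code for a missing diploid genotype.
MISSING = -1

_INT32_MISSING = np.iinfo(np.int32).min


class EmptyResultError(ValueError):
    """Raised when a read or filter step leaves nothing to work with."""


class FormatError(ValueError):
    """Raised on malformed input files."""


class DataInconsistencyError(ValueError):
    """Raised when constraints contradict the genotype data."""


@dataclass
class VariantTable:
    """Per-site metadata for one phasing region (single chromosome).

    Positions are 1-based as in VCF and strictly increasing; ``cm`` holds
    interpolated genetic positions (centimorgans), non-decreasing with ``pos``.
    """

    chrom: str
    pos: np.ndarray          # int64, bp
    ids: list
    ref: list
    alt: list
    cm: np.ndarray           # float64, centimorgans

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos[idx],
            ids=[self.ids[i] for i in idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            cm=self.cm[idx],
        )


@dataclass
class GenotypeMatrix:
    """N x L genotype codes (0 hom-ref / 1 het / 2 hom-alt / MISSING).

    ``phase_sets`` maps ``(individual, variant_index) -> (ps_id, allele)``
    where ``allele`` is the first-haplotype allele read from a phased GT.
    Entries exist only at het, non-missing genotypes.
    """

    codes: np.ndarray        # int8 [N, L]
    sample_ids: list
    phase_sets: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]


#: Sparse scaffold: (individual, variant_index) -> first-haplotype allele.
Scaffold = dict


@dataclass
class GeneticMap:
    """Ordered (bp, cM) anchor points for one chromosome."""

    pos: np.ndarray          # int64 bp, strictly increasing
    cm: np.ndarray           # float64, non-decreasing

    #: extrapolation rate beyond the anchors, cM per bp (1 cM/Mb).
    DEFAULT_RATE = 1e-6


def _parse_region(region):
    """'chr', 'chr:start-end' -> (chrom, start, end); end-exclusive in bp."""
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    try:
        lo, _, hi = span.partition("-")
        return chrom, int(lo), int(hi) + 1
    except ValueError as exc:
        raise FormatError(f"malformed region {region!r}") from exc


def _iter_region(vcf_path, region):
    chrom, start, end = _parse_region(region)
    vcf = VCF(str(vcf_path))
    try:
        for var in vcf:
            if chrom is not None and var.CHROM != chrom:
                continue
            if start is not None and not (start <= var.POS < end):
                continue
            yield vcf, var
    finally:
        vcf.close()


def _is_biallelic(var) -> bool:
    if len(var.ALT) != 1:
        return False
    alt = var.ALT[0]
    return bool(alt) and alt[0] != "<" and alt != "*"


def read_genotypes(vcf_path, region=None):
    """Read biallelic genotype records into (VariantTable, GenotypeMatrix).

    Multiallelic and duplicated-position records are skipped (counted in the
    log).  Phased het GTs with a PS value populate ``phase_sets``.
    """
    samples = None
    pos, ids, ref, alt = [], [], [], []
    chrom = None
    code_rows = []
    phase_sets = {}
    n_multi = n_dup = 0
    seen_pos = set()
    for vcf, var in _iter_region(vcf_path, region):
        if samples is None:
            samples = list(vcf.samples)
        if not _is_biallelic(var):
            n_multi += 1
            continue
        if (var.CHROM, var.POS) in seen_pos:
            n_dup += 1
            continue
        if chrom is not None and var.CHROM != chrom:
            raise FormatError(
                "multiple chromosomes in input; pass a region to select one"
            )
        chrom = var.CHROM
        seen_pos.add((var.CHROM, var.POS))
        l = len(pos)
        gts = var.genotypes
        try:
            ps = var.format("PS")
        except KeyError:   # PS not declared in the header
            ps = None
        row = np.empty(len(gts), dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                row[i] = MISSING
                continue
            row[i] = a + b
            if a + b == 1 and gt[2] and ps is not None:
                ps_val = int(ps[i][0])
                if ps_val != _INT32_MISSING:
                    phase_sets[(i, l)] = (ps_val, int(a))
        code_rows.append(row)
        pos.append(var.POS)
        ids.append(var.ID or ".")
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if n_multi or n_dup:
        logger.info(
            "skipped %d non-biallelic and %d duplicated-position records",
            n_multi, n_dup,
        )
    if not pos:
        raise EmptyResultError(f"no biallelic variants in {vcf_path} ({region})")
    order = np.argsort(np.asarray(pos), kind="stable")
    if not np.array_equal(order, np.arange(len(pos))):
        raise FormatError("VCF records are not position-sorted")
    vt = VariantTable(
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        ids=ids,
        ref=ref,
        alt=alt,
        cm=np.asarray(pos, dtype=np.float64) * GeneticMap.DEFAULT_RATE,
    )
    gm = GenotypeMatrix(
        codes=np.vstack(code_rows).T.copy(),
        sample_ids=samples,
        phase_sets=phase_sets,
    )
    return vt, gm


def read_haplotypes(vcf_path, region=None):
    """Read a fully phased panel into (VariantTable, 2R x L uint8 matrix)."""
    vt, gm = read_genotypes(vcf_path, region)
    haps = np.empty((2 * gm.n_samples, vt.n_sites), dtype=np.uint8)
    # re-read alleles: codes alone cannot recover phase
    l = 0
    for vcf, var in _iter_region(vcf_path, region):
        if not _is_biallelic(var):
            continue
        if l >= vt.n_sites or var.POS != vt.pos[l]:
            continue
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise FormatError(
                    f"missing genotype in haplotype panel at {var.POS}"
                )
            if a != b and not gt[2]:
                raise FormatError(
                    f"unphased het in haplotype panel at {var.POS}"
                )
            haps[2 * i, l] = a
            haps[2 * i + 1, l] = b
        l += 1
    return vt, haps


def read_scaffold(vcf_path, main_vt: VariantTable, main_gm: GenotypeMatrix,
                  region=None) -> Scaffold:
    """Read pre-phased het genotypes overlapping the main panel.

    Entries are kept only at (individual, variant) pairs present in both
    files, het in the main panel and phased ("|") in the scaffold.  Unphased
    scaffold records are skipped with a warning.
    """
    sample_index = {s: i for i, s in enumerate(main_gm.sample_ids)}
    site_index = {int(p): l for l, p in enumerate(main_vt.pos)}
    scaffold: Scaffold = {}
    n_unphased = 0
    for vcf, var in _iter_region(vcf_path, region):
        if not _is_biallelic(var):
            continue
        l = site_index.get(var.POS)
        if l is None or var.REF != main_vt.ref[l] or var.ALT[0] != main_vt.alt[l]:
            continue
        for j, name in enumerate(vcf.samples):
            i = sample_index.get(name)
            if i is None:
                continue
            gt = var.genotypes[j]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0 or a == b:
                continue
            if main_gm.codes[i, l] != 1:
                continue
            if not gt[2]:
                n_unphased += 1
                continue
            scaffold[(i, l)] = int(a)
    if n_unphased:
        logger.warning("skipped %d unphased scaffold het records", n_unphased)
    return scaffold


def read_genetic_map(path) -> GeneticMap:
    """Read a 3-column genetic map: (pos rate cM) or (chrom pos cM).

    A header line is skipped if present.  cM must be non-decreasing.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    pos, cm = [], []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                float(parts[1]), float(parts[2])
            except ValueError:
                if lineno == 0:
                    continue  # header
                raise FormatError(f"bad map line {lineno + 1}: {line!r}")
            if _is_number(parts[0]):
                # (pos, rate, cM) HapMap layout
                pos.append(int(float(parts[0])))
                cm.append(float(parts[2]))
            else:
                # (chrom, pos, cM)
                pos.append(int(float(parts[1])))
                cm.append(float(parts[2]))
    if not pos:
        raise FormatError(f"no usable anchors in genetic map {path}")
    pos_a = np.asarray(pos, dtype=np.int64)
    cm_a = np.asarray(cm, dtype=np.float64)
    if np.any(np.diff(pos_a) <= 0):
        raise FormatError("genetic map positions not strictly increasing")
    if np.any(np.diff(cm_a) < 0):
        raise FormatError("genetic map cM not monotone")
    return GeneticMap(pos=pos_a, cm=cm_a)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def interpolate_cm(gmap: GeneticMap, positions) -> np.ndarray:
    """Piecewise-linear cM at ``positions``; constant-rate extrapolation.

    Beyond the map ends the default 1 cM/Mb rate is used.
    """
    positions = np.asarray(positions, dtype=np.float64)
    out = np.interp(positions, gmap.pos.astype(np.float64), gmap.cm)
    rate = GeneticMap.DEFAULT_RATE
    below = positions < gmap.pos[0]
    above = positions > gmap.pos[-1]
    out[below] = gmap.cm[0] - (gmap.pos[0] - positions[below]) * rate
    out[above] = gmap.cm[-1] + (positions[above] - gmap.pos[-1]) * rate
    return out


def apply_qc_filters(gm: GenotypeMatrix, vt: VariantTable,
                     max_var_missing: float = 0.05,
                     max_ind_missing: float = 0.05):
    """Drop variants then individuals exceeding the missingness thresholds.

    The variant filter runs first; both use a strict ">" comparison, so a
    site or individual at exactly the threshold is retained.
    """
    miss = gm.codes == MISSING
    keep_var = miss.mean(axis=0) <= max_var_missing
    if not keep_var.any():
        raise EmptyResultError("QC removed every variant")
    codes = gm.codes[:, keep_var]
    keep_ind = (codes == MISSING).mean(axis=1) <= max_ind_missing
    if not keep_ind.any():
        raise EmptyResultError("QC removed every individual")
    logger.info(
        "QC removed %d/%d variants and %d/%d individuals",
        int((~keep_var).sum()), vt.n_sites,
        int((~keep_ind).sum()), gm.n_samples,
    )
    var_map = {int(old): new for new, old in enumerate(np.flatnonzero(keep_var))}
    ind_map = {int(old): new for new, old in enumerate(np.flatnonzero(keep_ind))}
    phase_sets = {
        (ind_map[i], var_map[l]): v
        for (i, l), v in gm.phase_sets.items()
        if i in ind_map and l in var_map
    }
    gm2 = GenotypeMatrix(
        codes=codes[keep_ind].copy(),
        sample_ids=[s for s, k in zip(gm.sample_ids, keep_ind) if k],
        phase_sets=phase_sets,
    )
    return gm2, vt.subset(np.flatnonzero(keep_var))


def intersect_with_reference(main: VariantTable, ref: VariantTable):
    """Align main-panel sites with a reference panel.

    Returns ``(main_idx, ref_idx, flip)``: records matched on
    (chrom, pos, ref, alt); allele-swapped records matched with ``flip`` set
    (reference-panel allele codes must be complemented); everything else is
    dropped.
    """
    ref_lookup = {}
    for j in range(ref.n_sites):
        ref_lookup[(int(ref.pos[j]), ref.ref[j], ref.alt[j])] = j
    main_idx, ref_idx, flip = [], [], []
    n_dropped = 0
    for i in range(main.n_sites):
        key = (int(main.pos[i]), main.ref[i], main.alt[i])
        j = ref_lookup.get(key)
        if j is not None:
            main_idx.append(i); ref_idx.append(j); flip.append(False)
            continue
        j = ref_lookup.get((int(main.pos[i]), main.alt[i], main.ref[i]))
        if j is not None:
            main_idx.append(i); ref_idx.append(j); flip.append(True)
            continue
        n_dropped += 1
    if not main_idx:
        raise EmptyResultError("no overlap between main and reference panel")
    if n_dropped:
        logger.info("dropped %d main-panel sites absent from reference", n_dropped)
    return (np.asarray(main_idx), np.asarray(ref_idx),
            np.asarray(flip, dtype=bool))


def write_phased_vcf(path, vt: VariantTable, haplotypes: np.ndarray,
                     sample_ids=None, pp=None) -> None:
    """Write phased haplotypes (2N x L, {0,1}) as a VCF with ``a|b`` GTs.

    ``pp`` (optional, N x L) adds a per-genotype phasing-certainty FORMAT
    field.  Round-trips through :func:`read_genotypes`.
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.ndim != 2 or haplotypes.shape[0] % 2:
        raise ValueError("haplotypes must be a 2N x L matrix")
    if not np.isin(haplotypes, (0, 1)).all():
        raise ValueError("haplotypes contain non-binary entries (incomplete?)")
    n = haplotypes.shape[0] // 2
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    opener = gzip.open if str(path).endswith(".gz") else open
    fmt = "GT" if pp is None else "GT:PP"
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={vt.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if pp is not None:
            fh.write('##FORMAT=<ID=PP,Number=1,Type=Float,'
                     'Description="Phasing certainty">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for l in range(vt.n_sites):
            cols = [vt.chrom, str(int(vt.pos[l])), vt.ids[l], vt.ref[l],
                    vt.alt[l], ".", "PASS", ".", fmt]
            for i in range(n):
                gt = f"{haplotypes[2 * i, l]}|{haplotypes[2 * i + 1, l]}"
                if pp is not None:
                    gt += f":{pp[i, l]:.4g}"
                cols.append(gt)
            fh.write("\t".join(cols) + "\n")
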