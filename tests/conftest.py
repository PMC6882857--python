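import numpy as np
import pytest

from phasekit import evalsim


def mean_ser(haps, truth, min_hets=2):
    """Mean switch error rate over all evaluable individuals."""
    out = []
    for i in range(truth.n_samples):
        t1, t2 = truth.pair(i)
        if int((t1 != t2).sum()) < min_hets:
            continue
        out.append(evalsim.switch_error_rate(
            (haps[2 * i], haps[2 * i + 1]), (t1, t2)))
    return float(np.mean(out))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_truth():
    """30 samples x 300 sites mosaic panel shared by fast tests."""
    return evalsim.simulate_population(
        n_founders=12, n_samples=30, n_sites=300, span_bp=400_000,
        recomb_per_bp=1e-6, maf_min=0.1, seed=11)


def write_vcf_text(path, text):
    path.write_text(text)
    return str(path)


SMALL_VCF = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tv1\tA\tG\t.\tPASS\t.\tGT:PS\t0/1:.\t0|1:7\t1/1:.
1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
1\t300\tv3\tG\tGA\t.\tPASS\t.\tGT\t0/1\t1|1\t0/0
"""
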