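import numpy as np
import pytest

from sweepscan.genodata import HaplotypePanel


def make_panel(matrix, positions=None, chrom="1", ancestral=None, pops=None):
    """Build a HaplotypePanel from a (n_hap, n_sites) 0/1 array."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_hap, n_sites = matrix.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if ancestral is None:
        ancestral = np.zeros(n_sites, dtype=np.int8)
    sample_ids = [f"s{k}" for k in range(n_hap // 2)]
    if pops is None:
        pop_of = {s: "pop1" for s in sample_ids}
    else:
        pop_of = {s: p for s, p in zip(sample_ids, pops)}
    return HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=[("A", "G")] * n_sites,
        matrix=matrix,
        ancestral=np.asarray(ancestral, dtype=np.int8),
        sample_ids=sample_ids,
        pop_of=pop_of,
    )


def random_panel(rng, n_hap=20, n_sites=30, two_pops=False):
    """Random polymorphic panel for property tests."""
    while True:
        mat = (rng.random((n_hap, n_sites)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
        p = mat.mean(axis=0)
        if np.all((p > 0) & (p < 1)):
            break
    pops = None
    if two_pops:
        half = n_hap // 4
        pops = ["A"] * half + ["B"] * (n_hap // 2 - half)
    return make_panel(mat, pops=pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


VCF_BODY = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
1\t100\t.\tA\tG\t.\t.\tAA=A\tGT\t0|1\t1|1
1\t200\t.\tC\tT\t.\t.\tAA=T\tGT\t0|0\t0|1
1\t300\t.\tG\tA\t.\t.\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def small_vcf(tmp_path):
    path = tmp_path / "small.vcf"
    path.write_text(VCF_BODY)
    return path
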