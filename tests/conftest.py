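import textwrap
import warnings

import numpy as np
import pytest

from gdassess.genomic_io import VariantTable

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=s1,length=200000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
    """
)


@pytest.fixture
def toy_vcf(tmp_path):
    """Five records: four biallelic SNPs and one tri-allelic to be skipped."""
    body = textwrap.dedent(
        """\
        s1\t101\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0
        s1\t250\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t0/1
        s1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t0/0
        s1\t450\t.\tT\tC\t.\tPASS\t.\tGT\t./.\t0/1
        s1\t900\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1/1
        """
    )
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.fixture
def empty_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text(VCF_HEADER)
    return path


def make_table(positions, genotypes, samples=None, scaffold="s1"):
    """Build a VariantTable from plain lists, silencing the sample-count warning."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if samples is None:
        samples = [f"ind{i}" for i in range(genotypes.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return VariantTable(
            samples=samples,
            scaffolds=[scaffold] * len(positions),
            positions=np.asarray(positions, dtype=np.int64),
            genotypes=genotypes,
        )
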