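"""Shared fixtures: tiny hand-written cohorts and the drug-map structures
used across the disruption and interaction tests. All fixtures are built
programmatically; nothing binary is stored."""

import numpy as np
import pytest

from pgxburden.model import DrugGeneMap, GenotypeMatrix, VariantKey


def make_matrix(calls, variants=None, populations=None, phased=None, samples=None):
    """Build a GenotypeMatrix from a nested list of (a, b) call pairs.

    ``calls[i][j]`` is the (allele, allele) pair of sample i at variant j;
    ``(-1, -1)`` marks a missing call.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape[:2]
    if variants is None:
        variants = [
            VariantKey("1", 100 * (j + 1), "A", "G", rsid=f"rs{j}") for j in range(m)
        ]
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    if phased is None:
        phased = np.ones((n, m), dtype=bool)
    return GenotypeMatrix(samples, populations, variants, calls, np.asarray(phased))


@pytest.fixture
def two_sample_matrix():
    """Two samples, one variant: calls 0/1 (unphased) and 1|1 (phased)."""
    return make_matrix(
        [[(0, 1)], [(1, 1)]],
        phased=[[False], [True]],
    )


@pytest.fixture
def sankey_drug_map():
    """Drug map mirroring a sulfonylurea with a sole metabolizing enzyme and
    an alpha-glucosidase inhibitor with four target genes."""
    entries = {
        ("glimepiride", "CYP2C9", "enzyme"),
        ("glimepiride", "ABCB11", "transporter"),
        ("miglitol", "GAA", "target"),
        ("miglitol", "GANAB", "target"),
        ("miglitol", "GANC", "target"),
        ("miglitol", "MGAM", "target"),
    }
    categories = {"glimepiride": "sulfonylurea", "miglitol": "alpha_glucosidase_inhibitor"}
    return DrugGeneMap(entries, categories)


@pytest.fixture
def vcf_text(tmp_path):
    """Write VCF text to a temp file and return its path."""

    def _write(body, name="test.vcf"):
        path = tmp_path / name
        path.write_text(body)
        return str(path)

    return _write


MINIMAL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1|1
"""

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t200\trs2\tC\tA,T\t.\t.\t.\tGT\t1/2\t0|2\t0/0
"""

NO_GT_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t.\t.\t.\tDP\t3\t5
"""
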