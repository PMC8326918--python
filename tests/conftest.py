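import numpy as np
import pytest

from qtlseq import f2sim, scan

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    "parent_short\tparent_long\tbulk_high\tbulk_low\n"
)


def vcf_line(chrom, pos, ref, alt, *samples):
    return "\t".join([chrom, str(pos), ".", ref, alt, ".", "PASS", ".",
                      "GT:AD:DP:GQ", *samples]) + "\n"


def sample(gt, ad, gq):
    return f"{gt}:{ad[0]},{ad[1]}:{ad[0] + ad[1]}:{gq}"


@pytest.fixture
def write_vcf(tmp_path):
    def _write(lines, name="test.vcf"):
        path = tmp_path / name
        path.write_text(VCF_HEADER + "".join(lines))
        return path
    return _write


@pytest.fixture(scope="session")
def null_ci_k50():
    """Shared simulated null quantile table for the study bulk size (k=50)."""
    return scan.simulate_null_ci(50, n_replicates=50_000, seed=7)


@pytest.fixture(scope="session")
def small_genome():
    """One 5-Mb chromosome at the rice-like 4 cM/Mb, 500 markers."""
    return f2sim.rice_like_genome(n_chromosomes=1, length_bp=5_000_000)
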