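import numpy as np
import pytest

from bulkmap.vario import PooledVariant, VariantTable


def pv(pos, chrom="Chr1", ref="A", alts=("G",), qual=100.0, qd=10.0,
       p1_gt=(0, 0), p2_gt=(1, 1), low_gt=(0, 1), high_gt=(0, 1),
       p1_ad=(20, 0), p2_ad=(0, 20), low_ad=(10, 10), high_ad=(10, 10)):
    """Factory for a well-formed informative variant record."""
    return PooledVariant(chrom, pos, ref, tuple(alts), qual, qd,
                         p1_gt, p2_gt, low_gt, high_gt,
                         tuple(p1_ad), tuple(p2_ad), tuple(low_ad), tuple(high_ad))


def table_of(*records):
    return VariantTable(list(records))


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##contig=<ID=Chr1,length=1000000>
##contig=<ID=Chr2,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tLOW\tHIGH
Chr1\t100\t.\tA\tG\t500.00\tPASS\tQD=25.00\tGT:AD:DP\t0/0:20,0:20\t1/1:0,22:22\t0/1:12,8:20\t0/1:9,11:20
Chr1\t200\t.\tC\tT,G\t300.00\tPASS\tQD=20.00\tGT:AD:DP\t0/0:18,0,0:18\t1/1:0,19,2:21\t0/1:10,8,1:19\t0/1:11,9,0:20
Chr1\t300\t.\tA\tAACGT\t400.00\tPASS\t.\tGT:AD:DP\t0/0:15,0:15\t1/1:0,17:17\t0/1:8,9:17\t0/1:7,8:15
Chr1\t400\t.\tA\t{INS51}\t350.00\tPASS\tQD=18.00\tGT:AD:DP\t0/0:16,0:16\t1/1:0,18:18\t0/1:9,9:18\t0/1:8,9:17
Chr2\t150\t.\tG\tA\t600.00\tPASS\tQD=30.00\tGT:AD:DP\t0/0:25,0:25\t1/1:0,24:24\t0/1:13,12:25\t0/1:12,13:25
""".replace("{INS51}", "A" + "CG" * 25 + "T")  # 52 bp allele: 51 bp insertion


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
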