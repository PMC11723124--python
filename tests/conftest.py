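import numpy as np
import pytest

from radpop import simdata
from radpop.vcfio import MISSING, LocusRecord, VariantMatrix

HANDWRITTEN_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tG\t.\t.\t.\tGT:DP:GQ:AD\t0/1:30:99:15,15\t0/0:25:80:25,0
chr1\t200\trs1\tC\tT\t.\t.\t.\tGT:DP:GQ:AD\t1/1:40:90:0,40\t./.:.:.:.
chr1\t300\t.\tG\tA\t.\t.\t.\tGT:DP:GQ:AD\t0/1/1/1:60:50:15,45\t0/1:12:22:6,6
"""


@pytest.fixture
def handwritten_vcf(tmp_path):
    path = tmp_path / "hand.vcf"
    path.write_text(HANDWRITTEN_VCF)
    return path


def make_matrix(dosage, call_ploidy=None, dp=None, gq=None, ad=None, samples=None):
    """Build a VariantMatrix from small python arrays for tests."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_loci, n_samples = dosage.shape
    if call_ploidy is None:
        call_ploidy = np.where(dosage == MISSING, MISSING, 2).astype(np.int16)
    else:
        call_ploidy = np.asarray(call_ploidy, dtype=np.int16)
    dp = (
        np.full_like(dosage, 30, dtype=np.int32)
        if dp is None
        else np.asarray(dp, dtype=np.int32)
    )
    gq = (
        np.full_like(dosage, 99, dtype=np.int32)
        if gq is None
        else np.asarray(gq, dtype=np.int32)
    )
    if ad is None:
        ad_ref = np.full_like(dosage, MISSING, dtype=np.int32)
        ad_alt = np.full_like(dosage, MISSING, dtype=np.int32)
    else:
        ad_ref, ad_alt = (np.asarray(a, dtype=np.int32) for a in ad)
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = [
        LocusRecord("chr1", 100 * (i + 1), *bases[i % 4]) for i in range(n_loci)
    ]
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    return VariantMatrix(
        loci=loci,
        samples=samples,
        dosage=dosage,
        call_ploidy=call_ploidy,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two divergent diploid populations (F=0.3), 8 samples each, 200 loci."""
    cfg = simdata.SimConfig(
        n_loci=200,
        populations=[
            simdata.PopulationConfig("A", 8, divergence=0.3),
            simdata.PopulationConfig("B", 8, divergence=0.3),
        ],
        seed=2,
    )
    return simdata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_ploidy_cohort():
    """Small 2n/3n/4n cohort at depth 60 for ploidy tests."""
    cfg = simdata.SimConfig(
        n_loci=1200,
        populations=[
            simdata.PopulationConfig("d2", 3, divergence=0.05, ploidy=2),
            simdata.PopulationConfig("d3", 3, divergence=0.05, ploidy=3),
            simdata.PopulationConfig("d4", 3, divergence=0.05, ploidy=4),
        ],
        depth_mean=60,
        seed=7,
    )
    return simdata.simulate_cohort(cfg)


TOY_GFF = """\
##gff-version 3
chr1\tsrc\tgene\t101\t155\t.\t+\t.\tID=gene1
chr1\tsrc\tmRNA\t101\t155\t.\t+\t.\tID=mrna1;Parent=gene1
chr1\tsrc\texon\t101\t131\t.\t+\t.\tID=e1;Parent=mrna1
chr1\tsrc\texon\t141\t155\t.\t+\t.\tID=e2;Parent=mrna1
chr1\tsrc\tfive_prime_UTR\t101\t110\t.\t+\t.\tID=u5;Parent=mrna1
chr1\tsrc\tCDS\t111\t131\t.\t+\t0\tID=c1;Parent=mrna1
chr1\tsrc\tCDS\t141\t149\t.\t+\t0\tID=c2;Parent=mrna1
chr1\tsrc\tthree_prime_UTR\t150\t155\t.\t+\t.\tID=u3;Parent=mrna1
"""


def toy_genome() -> str:
    """300 bp reference; codon 1 of gene1 is TGG, codon 2 is GCT."""
    s = list("A" * 300)
    s[110:113] = "TGG"
    s[113:116] = "GCT"
    return "".join(s)


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory):
    d = tmp_path_factory.mktemp("annot")
    fasta = d / "toy.fa"
    fasta.write_text(">chr1\n" + toy_genome() + "\n")
    gff = d / "toy.gff3"
    gff.write_text(TOY_GFF)
    from radpop import annotate

    return annotate.load_annotation(gff, fasta)
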