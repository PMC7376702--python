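import numpy as np
import pytest

from sweepscan import GenotypeMatrix, PopulationAssignment


def make_gm(dosage, pos0=None, chrom="chr1", sample_prefix="s"):
    """GenotypeMatrix from a samples × sites dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if pos0 is None:
        pos0 = np.arange(n_sites) * 100 + 100
    chrom_arr = np.full(n_sites, chrom, dtype=object) \
        if isinstance(chrom, str) else np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{k + 1}" for k in range(n_samples)],
        chrom=chrom_arr,
        pos0=np.asarray(pos0, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        dosage=dosage,
    )


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, records, samples=("s1", "s2", "s3", "s4", "s5")):
    """Write a VCF from (chrom, pos1, ref, alt, [gt...]) tuples."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


@pytest.fixture
def small_vcf(tmp_path):
    """5 samples; 5 clean biallelic SNPs plus one multiallelic, one indel
    and one site with a missing call (20 % missingness, at the default
    filter boundary so it is retained)."""
    records = [
        ("chr1", 100, "A", "G", ["0/0", "0/1", "1/1", "0/0", "0/1"]),
        ("chr1", 200, "C", "T", ["0/1", "0/1", "0/0", "1/1", "0/0"]),
        ("chr1", 300, "G", "A,T", ["0/1", "0/0", "0/0", "0/0", "0/0"]),
        ("chr1", 400, "T", "TA", ["0/0", "0/1", "0/0", "0/0", "0/0"]),
        ("chr1", 500, "G", "C", ["./.", "0/1", "1/1", "0/0", "0/1"]),
        ("chr2", 150, "A", "T", ["1/1", "1/1", "0/0", "0/1", "0/0"]),
        ("chr2", 250, "C", "G", ["0/0", "0/0", "0/1", "0/0", "1/1"]),
    ]
    return write_vcf_text(tmp_path / "small.vcf", records)


@pytest.fixture
def two_group_pops():
    samples = [f"b{k}" for k in range(1, 4)] + [f"n{k}" for k in range(1, 7)]
    mapping = {s: ("black" if s.startswith("b") else "nonblack")
               for s in samples}
    return PopulationAssignment(mapping, "black", "nonblack")
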