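import numpy as np
import pytest

from introscan.panel_io import GenotypeMatrix, VariantSite

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr6B>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def make_vcf(tmp_path, records, samples=("s1", "s2", "s3"), name="test.vcf"):
    """Write a small VCF; records are (chrom, pos, ref, alt, gts...) tuples."""
    path = tmp_path / name
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines = [VCF_HEADER + cols]
    for chrom, pos, ref, alt, *gts in records:
        line = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t."
        if gts:
            line += "\tGT\t" + "\t".join(gts)
        lines.append(line)
    path.write_text("\n".join(lines) + "\n")
    return path


def matrix_from_columns(positions, columns, accessions, chrom="chr6B"):
    """Build a GenotypeMatrix from per-accession genotype-code columns."""
    calls = np.array(columns, dtype=np.int8).T
    sites = [VariantSite(chrom, int(p), "A", "G") for p in positions]
    return GenotypeMatrix(sites=sites, accessions=list(accessions), calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
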