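#!/usr/bin/env python
"""Assign the donor lineage of the alien segment by neighbor joining.

Restricts the panel genotypes to the detected segment, computes SNP
p-distances over all accession pairs, builds the NJ tree, and reports
whether the query line attaches inside the donor clade. Writes the
distance matrix and Newick tree under results/origin/.
"""

from pathlib import Path

from introscan.panel_io import Group, read_genotype_table, read_panel_metadata
from introscan.phylogeny import (
    neighbor_joining,
    p_distance_matrix,
    query_neighbor_clade,
    write_distance_tsv,
    write_newick,
)
from introscan.scan import restrict_to_region

IN = Path("results/inputs")
OUT = Path("results/origin")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mat = read_genotype_table(IN / "panel.vcf", format="vcf")
    panel = read_panel_metadata(IN / "panel_accessions.tsv")

    bed = (OUT / "segment.bed").read_text().split()
    chrom, start, end = bed[0], int(bed[1]) + 1, int(bed[2])
    seg = restrict_to_region(mat, chrom, start, end)
    print(f"distances computed on {seg.n_sites} SNPs inside {chrom}:{start:,}-{end:,}")

    D = p_distance_matrix(seg)
    write_distance_tsv(D, OUT / "distances.tsv")
    tree = neighbor_joining(D)
    write_newick(tree, OUT / "tree.nwk")

    query = next(a.id for a in panel if a.group is Group.QUERY)
    donors = {a.id for a in panel if a.group is Group.DONOR_CANDIDATE}
    in_clade = query_neighbor_clade(tree, query, donors)
    print(f"query line {query!r} attaches inside the donor clade: {in_clade}")

    qi = D.taxa.index(query)
    nearest = sorted(
        ((D.d[qi, j], t) for j, t in enumerate(D.taxa) if t != query)
    )[:3]
    print("nearest accessions by p-distance:")
    for d, t in nearest:
        print(f"  {t}: {d:.4f}")


if __name__ == "__main__":
    main()
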