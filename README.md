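# introscan

Tools for characterizing an **alien chromosomal introgression** in wheat
from SNP panels, and for working with the genetic material it carries:

1. **Origin scan** — classify biallelic SNPs of a multi-species panel into
   donor-diagnostic, query-rare, shared-wheat and uninformative categories;
   locate the contiguous run of query-shared donor-diagnostic SNPs that
   marks the alien segment; and bracket the translocation breakpoint
   between the last supporting SNP and the first wheat-type SNP beyond it.
2. **Donor phylogeny** — p-distances (genotype mismatch fractions) between
   all accession pairs over the SNPs inside the segment, and a
   Saitou–Nei neighbor-joining tree that places the query line relative to
   the candidate donor species.
3. **Linkage mapping** — Stakman 0–4 infection-type parsing, Pearson χ²
   segregation tests against Mendelian ratios (3:1 for a dominant gene),
   minimal recombinant-gamete counting in a coupling-phase F2, and genetic
   maps with cM = 100 · recombinants/gametes (no mapping function; all
   distances here are ≪ 10 cM).
4. **CAPS/InDel marker evaluation** — degenerate (IUPAC) restriction-site
   scanning, linear in-silico digestion, gel-level diagnosability verdicts
   and enzyme suggestions for a SNP (e.g., AvaI = C^YCGRG), plus
   marker-panel summaries over germplasm collections.
5. **Synthetic data** — seeded generators for all of the above with ground
   truth, so the whole pipeline is testable without any external download.

The intended users are wheat geneticists and breeders working with alien
introgression lines: the typical object of study is a resistance-gene
segment transferred from a wild relative (here, an *Aegilops* Sitopsis-type
donor) into tetraploid/hexaploid wheat.

## Worked example

The numbered scripts under `analysis/` run the full desk-scale study:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_scan_introgression.py
python analysis/03_donor_phylogeny.py
python analysis/04_map_resistance_genes.py
python analysis/05_evaluate_caps_markers.py
```

`02_scan_introgression.py` prints, for the default simulated panel
(22 accessions, 9,294 SNPs, alien segment spanning the first 687 Mb of a
700 Mb chromosome):

```
per-category SNP counts: {'DONOR_DIAGNOSTIC': 8311, 'QUERY_RARE': 54, 'SHARED_WHEAT': 880, 'UNINFORMATIVE': 49}
donor-diagnostic SNPs shared with the query line: 8152
alien segment: chr6B:126,859-686,943,622 (~686.94 Mb, 8152 supporting SNPs)
translocation breakpoint bracket: [686,943,622, 688,161,097] bp
simulated true boundary 687,020,000 bp inside the bracket: True
```

i.e. ~8.3k SNPs are fixed in the donor group and absent from every
polyploid wheat reference; the query line shares them over a single
contiguous run whose end, together with the first wheat-type SNP beyond
it, brackets the true translocation breakpoint. `03_donor_phylogeny.py`
then reports that the query attaches inside the donor clade of the NJ
tree (its nearest neighbors by p-distance are the donor accessions), and
`04_map_resistance_genes.py` prints the 3:1 segregation test
(e.g. `140 resistant : 48 susceptible -> chi2 = 0.03, p = 0.866`) and the
marker–gene map. `05_evaluate_caps_markers.py` digests the 1118-bp marker
amplicon: the resistance-associated allele cuts to 418 + 700 bp bands
while the susceptible allele stays a single 1118-bp band — a diagnostic
CAPS assay.

The same stages are available as a CLI (`introscan simulate|scan|tree|map|caps|io|run`),
e.g.:

```bash
introscan scan --vcf panel.vcf --panel accessions.tsv --out-bed seg.bed --out-tsv sites.tsv
```

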