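#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes, under results/inputs/:
  panel.vcf / panel_accessions.tsv — a 22-accession multi-species SNP panel
      (4 donor candidates, 17 polyploid wheat references, 1 query line
      carrying a ~687 Mb alien segment on a 700 Mb chromosome, 9,294 SNPs);
  panel_truth.json — the generator's ground truth for the panel;
  population.tsv — a 188-plant coupling-phase F2 population segregating
      3:1 for a dominant resistance gene flanked by two markers;
  amplicon_ref.fa / amplicon_alt.fa — the 1118-bp CAPS marker amplicon
      pair (AvaI site at base 418 present/destroyed).
"""

import json
from pathlib import Path

from introscan.caps import AVAI
from introscan.linkage import write_population_tsv
from introscan.panel_io import write_genotype_vcf, write_panel_metadata
from introscan.synthetic import (
    PanelSimConfig,
    PopSimConfig,
    simulate_amplicon_pair,
    simulate_mapping_population,
    simulate_species_panel,
)

SEED = 7
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel_cfg = PanelSimConfig(seed=SEED)
    mat, truth = simulate_species_panel(panel_cfg)
    write_genotype_vcf(mat, OUT / "panel.vcf")
    write_panel_metadata(truth.panel, OUT / "panel_accessions.tsv")
    (OUT / "panel_truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "segment_interval": list(truth.segment_interval),
                "n_sites": mat.n_sites,
                "n_donor_diagnostic": sum(
                    1 for c in truth.categories if c.name == "DONOR_DIAGNOSTIC"
                ),
            },
            indent=2,
        )
        + "\n"
    )
    print(f"panel: {mat.n_sites} SNPs x {mat.n_accessions} accessions -> {OUT/'panel.vcf'}")

    pop_cfg = PopSimConfig(seed=SEED)
    plants, pop_truth = simulate_mapping_population(pop_cfg)
    write_population_tsv(plants, OUT / "population.tsv")
    print(
        f"population: {len(plants)} F2 plants, true recombinant gametes per "
        f"interval {pop_truth.interval_recombinants.tolist()} -> {OUT/'population.tsv'}"
    )

    ref, alt = simulate_amplicon_pair(1118, AVAI, 418, seed=SEED)
    (OUT / "amplicon_ref.fa").write_text(f">pku6B3127_resistant\n{ref}\n")
    (OUT / "amplicon_alt.fa").write_text(f">pku6B3127_susceptible\n{alt}\n")
    print(f"amplicons: 1118 bp pair (AvaI site at 418) -> {OUT}/amplicon_*.fa")


if __name__ == "__main__":
    main()
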