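# Methods

## Scope and data model

The package analyzes genotype tables, not reads: upstream trimming,
alignment and variant calling are out of scope, and every input is either
a standard text format (VCF with GT fields, TSV genotype/population
tables, FASTA amplicons, BED) or produced by the built-in generators.
Coordinates are 1-based inclusive internally (the VCF convention); BED
export converts to 0-based half-open. Genotype calls are coded
HOM_REF/HET/HOM_ALT/MISSING; heterozygous calls are retained by the
readers and interpreted only by downstream policy.

## SNP classification

For each biallelic site, the classifier looks at the non-reference (alt)
allele across three accession groups — donor candidates, polyploid wheat
references, and the single query line:

* **DONOR_DIAGNOSTIC** — alt present in *all* non-missing donor
  accessions, absent from *all* non-missing references, with at least one
  non-missing call per group and per-group missing fractions within the
  policy limit. These are the species-diagnostic SNPs whose presence in
  the query marks donor chromatin.
* **SHARED_WHEAT** — alt present in ≥ 1 reference: an ordinary wheat
  polymorphism.
* **QUERY_RARE** — the query carries the alt, no reference does, but the
  donor condition fails: a polymorphism private to the query relative to
  polyploid wheat.
* **UNINFORMATIVE** — everything else, including monomorphic columns.

The categories are mutually exclusive and exhaustive, checked in that
order. "Absence" is per-allele: no non-missing reference carries the alt
under the het policy.

Two policy knobs matter. `het_carries` (default true) counts a HET call
as carrying the alt allele — RNA-seq genotypes of a polyploid make
hom/het dosage unreliable, so presence is the robust reading; it is
configurable to hom-only. `max_missing_fraction` (default 0.0) bounds the
tolerated missing fraction in the donor and reference groups for a site
to remain eligible for diagnostic status. The strict default reflects
complete panels; with missing data the caller should raise it (e.g. 0.25
for a 4-donor group tolerates one missing donor). Under missingness,
errors are conservative by construction: a site can lose its diagnostic
status but a non-diagnostic truth site can never gain it, because absence
of calls never creates alt alleles.

## Segment detection and breakpoint bracketing

Supporting sites are donor-diagnostic SNPs whose alt allele the query
carries. The detector reports the longest run of supporting sites (bp
span; ties broken by larger support count, then more distal start)
satisfying:

* consecutive supporting SNPs ≤ `max_gap_bp` apart (default 10 Mb);
* at least `min_support` supporting SNPs (default 20);
* every `window_bp` tile (default 1 Mb) *fully contained* in the run that
  holds ≥ 1 classified SNP is at least `min_window_fraction` (default
  0.5) diagnostic.

Windows are absolute tiles anchored at coordinate 1 rather than windows
re-anchored on each candidate run. This makes a window's pass/fail status
a property of the data alone, which is both easier to reason about and
allows an exact search: supporting sites are first split into maximal
gap-bounded blocks, and within each block any qualifying run must lie
between two consecutive failing tiles, so only those snapped intervals
need examination. The implementation is verified against an exhaustive
oracle over all contiguous runs in the tests.

The defaults were chosen to be robust on the synthetic truth at the
panel's SNP density (~13 classified SNPs per Mb): a real alien segment
produces near-saturated diagnostic windows, while scattered
misclassifications cannot assemble 20 supports within the gap ceiling.
With ~0.9 diagnostic fraction inside the segment, roughly one tile per
chromosome still dips below 50% by sampling noise; the reported run then
stops at that tile, which can shorten the *reported span* while leaving
the breakpoint bracket — the quantity of scientific interest — intact.

The bracket is `[breakpoint_lo, breakpoint_hi]` with `breakpoint_lo` the
last supporting SNP. For `breakpoint_hi` the implementation takes the
first SNP beyond the run at which the query itself shows wheat-type
evidence: a shared-wheat SNP whose alt allele the query carries. A
shared-wheat SNP as such is not discordant evidence — ordinary wheat
polymorphism also segregates *inside* an alien segment among the
reference accessions, and using any shared site would close the bracket
prematurely; the query's own genotype at the site is what places its
chromatin. When no such site exists the sentinel `chrom_length + 1` is
used. On the worked example ending at 687,016,683 bp with the next
wheat-type SNP at 688,295,787 bp, the bracket is exactly those two
positions.

## Distances and neighbor joining

p-distance between two accessions is the mismatch fraction of genotype
codes over sites called in both, with HET-vs-HOM weighted 0.5 (allele
sharing; configurable to 1.0). Distances are computed directly from the
SNP matrix — the tree input *is* a SNP set, so realignment would add
nothing. Pairs sharing fewer than `min_overlap` sites (default 50) are an
error rather than a noisy estimate.

Neighbor joining is the standard Saitou–Nei agglomeration on
Q(i,j) = (n−2)d(i,j) − r_i − r_j with deterministic lowest-index
tie-breaking. Negative branch lengths are clamped to zero with the
deficit moved to the sister branch, preserving path lengths through the
join; the final three-taxon star uses the closed form with plain
clamping. On additive matrices the tree reproduces all pairwise path
lengths to 1e-9 and matches scikit-bio's independent NJ topology
(cross-checked in tests, never used as the implementation). Newick output
carries branch lengths at 6 significant digits and quotes names
containing metacharacters.

"Query inside the donor clade" is judged rooting-independently: some
bipartition of the unrooted tree must separate the query plus a nonempty
subset of donors (and nothing else) from the rest.

## Infection types, segregation and genetic maps

Stakman infection-type strings are reduced to their dominant numeral:
modifiers (`;`, `+`, `−`) are ignored, range scores like `3-4` take the
larger numeral, a pure fleck (`;` / `0;`) is class 0, and anything
unparseable raises — a bad score is never silently susceptible. Resistant
means class ≤ `resistance_threshold` (default 2 on the 0–4 scale).

Segregation tests use the uncorrected Pearson χ² with df = 1 and an
upper-tail p from the χ² distribution; no Yates correction, which is the
convention the reproduced worked examples follow.

F3 progeny tests call the F2 genotype at the resistance locus: all
resistant → RR, all susceptible → rr, both → Rr. Families below
`min_family_size` (default 12) return UNKNOWN with a warning: an Rr
family of n segregates no susceptible plant with probability 0.75^n,
which at n = 12 is already ~3% — smaller families cannot separate RR
from Rr reliably.

Recombinant gametes are counted per plant as the minimum over all gamete
pairs consistent with the observed two-locus genotype (equivalently
|donor-allele dose difference| between the loci). The phase-ambiguous
double heterozygote resolves to 0 recombinants; at sub-centimorgan
distances the double-recombinant reading has probability O(r²) and is
negligible. Genetic distance is cM = 100 · recombinants/gametes with no
Haldane/Kosambi correction — at the distances involved (< ~3 cM) the
correction is below the printed rounding. cM and percentages round half
away from zero to 2 and 1 decimals respectively, matching how such
tables are printed. Loci are ordered by their physical anchor (no
multipoint ordering); zero-recombinant intervals collapse into
co-segregation groups.

The minimal-recombination estimator is slightly conservative: a plant
whose two gametes recombined in the same interval in opposite phases
(probability r²/2) scores 0 instead of 2, giving the estimator a
relative bias of about r/2. At the simulated design sizes (r ≤ 0.05,
2,000 gametes) this bias is an order of magnitude below the binomial
sampling error of a single estimate, which is the resolution at which
recovery is asserted.

## CAPS and InDel markers

Recognition patterns are IUPAC strings matched with overlaps on the top
strand; non-palindromic patterns are additionally matched against the
reverse complement with positions mapped back to top-strand coordinates
(IUPAC-palindromic patterns like AvaI's CYCGRG need no second pass).
Digestion is linear (PCR amplicons): the top-strand cut falls
`cut_offset` bases after the recognition start, bottom-strand matches use
the mirrored offset, duplicate and end-of-molecule cuts are dropped, and
fragment lengths always sum to the amplicon length (property-tested, and
cross-checked against Biopython's AvaI catalysis).

A assay is **diagnostic** when a gel could tell the alleles apart:
fragments shorter than `min_resolvable_diff` (default 20 bp, a standing
for agarose resolution) are treated as invisible, and the visible
patterns must differ in band count or in at least one band by ≥ that
threshold. This refines a naive multiset comparison: an allele that
merely gains a cut 3–4 bp from an existing one changes the fragment
*multiset* but not the observable gel pattern. Enzyme suggestion filters
the shipped enzyme table (an editable TSV seeded with AvaI and a few
common cutters; no external database needed) to enzymes whose recognition
window covers the SNP and whose assay is diagnostic, ranked by the
smallest band difference a gel must resolve. InDel markers compare
product lengths against the same threshold. Methylation sensitivity,
star activity and partial digestion are out of scope.

## Synthetic data: what it emulates, and what it does not

`simulate_species_panel` mirrors the study panel: 4 donor-candidate
accessions, 17 polyploid wheat references, one query line, 9,294 SNPs on
a 700 Mb chromosome, and an alien segment spanning (1, 687.02 Mb). Each
site is independently donor-diagnostic with probability 0.9 (the
diagnostic share observed in such panels), otherwise a wheat polymorphism
with probability 0.9 of the remainder, otherwise a query-private variant
(inside the segment) or monomorphic. Donors share the derived allele at
diagnostic sites; references never carry it; the query carries it exactly
inside the segment. Inside the segment the query never carries the wheat
alt allele (its chromatin there is donor-derived); outside it does with
probability 0.5. Missingness is uniform at `missing_rate`.

Deliberately *not* modeled: linkage disequilibrium and coalescent
structure within species, genotyping error beyond uniform missingness,
multiple introgressions, and ancestral-state polarity. Passing tests
therefore show that the algorithms recover the signal their definitions
target, not that real RNA-seq panels are this clean.

`simulate_mapping_population` draws each F2 plant as two independent
gametes with independent per-interval crossovers (no interference —
unobservable at these distances) in coupling phase, dominant resistance,
optional phenotype error, and records true per-interval recombinant
counts. A deterministic forced-placement mode (at most one recombinant
gamete per plant, alternating parental phase) exists solely to
reconstruct printed worked examples such as 1 recombinant in 376 gametes
→ 0.27 cM.

`simulate_amplicon_pair` rejection-samples a background free of
incidental recognition sites (capped at 10,000 attempts), plants one
concrete expansion of the degenerate site in one allele and a single-base
change abolishing it in the other (or an indel), and verifies the final
geometry before returning.

All generators are pure functions of their config including the seed.

## Pipeline, determinism and problem sizes

`run_origin_analysis` / `run_mapping_analysis` chain the stages, write
machine-readable summaries plus the resolved configuration and a log that
names every parameter actually used, and are byte-reproducible under a
fixed seed. Exit codes for scripts: 0 success, 2 input error, 3 no-call.

Simulation-backed checks run at these sizes: 50 seeded panels (9,294
sites × 22 accessions) for breakpoint-bracket recovery; 100 replicates ×
3 recombination fractions at 2,000 gametes for map-distance recovery;
1,000 random digests for fragment-length conservation. These sizes keep
the whole suite in the low tens of seconds on one CPU while leaving the
binomial arithmetic of the assertions meaningful.

## Known limitations

* The χ² worked values are reproduced at 2 d.p. except one published
  statistic (91R:45S vs 3:1) that prints as 4.75 from the uncorrected
  Pearson formula; no single rounding convention reproduces all four
  published values simultaneously.
* Breakpoint brackets are only as tight as the local SNP spacing; the
  detector brackets, it does not interpolate.
* The windowed-density rule can truncate the *reported span* at a
  low-density window while the bracket stays correct (see above).
* Distances are p-distances; no multiple-hit correction, so branch
  lengths understate divergence for distant taxa. Bootstrap support is
  out of scope.
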