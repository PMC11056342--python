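"""Seeded generators for every input the pipeline consumes, with ground truth.

Three generators mirror the three experimental designs the analysis rests
on:

* a multi-species SNP panel in which a query line carries one contiguous
  donor-derived chromosome segment (the origin analysis);
* a coupling-phase F2 mapping population segregating 3:1 for a dominant
  resistance gene, with codominant markers at known recombination
  fractions (the linkage analysis);
* amplicon pairs differing by a SNP inside (or an indel independent of) a
  degenerate restriction recognition site (the CAPS/InDel markers).

All generators are pure functions of their config, seed included, and
return the truth bookkeeping (per-site categories, per-interval recombinant
gamete counts, planted site coordinates) that downstream tests treat as the
oracle.

Default panel composition follows the study design the generators emulate:
four donor-candidate accessions (two each of the two sister donor species),
seventeen polyploid wheat references (wild emmer, durum and fifteen
hexaploid lines), one query introgression line, and an alien segment
occupying roughly the first 687 Mb of a 700 Mb chromosome with ~9,300
SNP sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caps import RestrictionEnzyme, IUPAC, find_recognition_sites
from .linkage import InfectionType, PlantRecord, classify_phenotype
from .panel_io import (
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    Group,
    PanelAccession,
    VariantSite,
)
from .scan import SiteCategory

_R_ITS = ("0;", ";1-", "1")
_S_ITS = ("3+", "4", "3-4")


# ---------------------------------------------------------------------------
# species panel


@dataclass(frozen=True)
class PanelSimConfig:
    """Conditions of the simulated multi-species SNP panel."""

    seed: int
    n_donor: int = 4
    n_reference: int = 17
    chrom: str = "chr6B"
    chrom_length: int = 700_000_000
    n_sites: int = 9_294
    segment_interval: tuple[int, int] = (1, 687_020_000)
    donor_divergence: float = 0.9  # P(site is donor-diagnostic type)
    background_polymorphism: float = 0.9  # P(wheat polymorphism | not donor type)
    query_rare_rate: float = 0.5  # P(query-private variant | residual, in segment)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("donor_divergence", "background_polymorphism", "query_rare_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        s, e = self.segment_interval
        if not 1 <= s <= e <= self.chrom_length:
            raise ValueError(f"segment {self.segment_interval} outside chromosome")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass
class PanelTruth:
    categories: list[SiteCategory]  # truth category per site (complete-data)
    query_in_segment: np.ndarray  # bool per site: query carries donor chromatin
    segment_interval: tuple[int, int]
    panel: list[PanelAccession]
    query_id: str


def simulate_species_panel(cfg: PanelSimConfig) -> tuple[GenotypeMatrix, PanelTruth]:
    """Simulate the panel genotypes and the per-site truth labels.

    Donor accessions share the derived allele at donor-diagnostic sites and
    no polyploid reference ever carries it; the query carries it iff the
    site lies inside the alien segment. Wheat polymorphisms (alt allele in
    >=1 reference) are sprinkled genome-wide; inside the segment the
    query's chromatin is donor-derived, so it never carries the wheat alt
    allele there. Residual sites are query-private variants (inside the
    segment) or monomorphic columns.
    """
    rng = np.random.default_rng(cfg.seed)
    n_acc = cfg.n_donor + cfg.n_reference + 1

    # sample distinct positions without materializing the coordinate range
    pos_set = np.unique(rng.integers(1, cfg.chrom_length + 1, size=cfg.n_sites))
    while pos_set.size < cfg.n_sites:
        extra = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_sites - pos_set.size)
        pos_set = np.unique(np.concatenate([pos_set, extra]))
    positions = pos_set
    in_seg = (positions >= cfg.segment_interval[0]) & (positions <= cfg.segment_interval[1])

    donors = [f"donor_{i+1:02d}" for i in range(cfg.n_donor)]
    refs = [f"wheat_{i+1:02d}" for i in range(cfg.n_reference)]
    query = "query"
    panel = (
        [PanelAccession(a, "donor_species", Group.DONOR_CANDIDATE) for a in donors]
        + [PanelAccession(a, "polyploid_wheat", Group.POLYPLOID_REFERENCE) for a in refs]
        + [PanelAccession(query, "introgression_line", Group.QUERY)]
    )
    d_idx = np.arange(cfg.n_donor)
    r_idx = np.arange(cfg.n_donor, cfg.n_donor + cfg.n_reference)
    q_idx = n_acc - 1

    u = rng.random(cfg.n_sites)
    is_donor_type = u < cfg.donor_divergence
    rest = ~is_donor_type
    is_wheat_type = rest & (rng.random(cfg.n_sites) < cfg.background_polymorphism)
    residual = rest & ~is_wheat_type
    is_rare_type = residual & in_seg & (rng.random(cfg.n_sites) < cfg.query_rare_rate)

    calls = np.full((cfg.n_sites, n_acc), HOM_REF, dtype=np.int8)
    categories: list[SiteCategory] = []
    for i in range(cfg.n_sites):
        if is_donor_type[i]:
            calls[i, d_idx] = HOM_ALT
            if in_seg[i]:
                calls[i, q_idx] = HOM_ALT
            categories.append(SiteCategory.DONOR_DIAGNOSTIC)
        elif is_wheat_type[i]:
            carriers = rng.random(cfg.n_reference) < 0.5
            if not carriers.any():
                carriers[rng.integers(cfg.n_reference)] = True
            calls[i, r_idx[carriers]] = HOM_ALT
            if not in_seg[i] and rng.random() < 0.5:
                calls[i, q_idx] = HOM_ALT
            categories.append(SiteCategory.SHARED_WHEAT)
        elif is_rare_type[i]:
            calls[i, q_idx] = HOM_ALT
            categories.append(SiteCategory.QUERY_RARE)
        else:
            categories.append(SiteCategory.UNINFORMATIVE)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    # ref/alt alleles per site (unequal by construction)
    bases = np.array(list("ACGT"))
    ref_b = rng.integers(0, 4, size=cfg.n_sites)
    alt_b = (ref_b + rng.integers(1, 4, size=cfg.n_sites)) % 4

    sites = [
        VariantSite(cfg.chrom, int(p), bases[ref_b[i]], bases[alt_b[i]])
        for i, p in enumerate(positions)
    ]
    mat = GenotypeMatrix(sites=sites, accessions=donors + refs + [query], calls=calls)
    truth = PanelTruth(
        categories=categories,
        query_in_segment=in_seg,
        segment_interval=cfg.segment_interval,
        panel=panel,
        query_id=query,
    )
    return mat, truth


# ---------------------------------------------------------------------------
# mapping population


@dataclass(frozen=True)
class PopSimConfig:
    """Conditions of the simulated coupling-phase F2 population.

    ``loci`` are in map order and include the resistance gene; ``r``
    gives the recombination fraction of each adjacent interval. The default
    geometry mirrors a distal resistance locus completely linked to one
    marker and ~0.27 cM from its other flank. ``forced_recombinants``
    (interval index -> gamete count) switches to a deterministic placement
    mode that reconstructs printed worked examples exactly.
    """

    seed: int
    n_plants: int = 188
    loci: tuple[str, ...] = ("pku6B165", "R_gene", "pku6B97F")
    gene: str = "R_gene"
    r: tuple[float, ...] = (0.0, 0.0027)
    phenotype_error: float = 0.0
    forced_recombinants: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("empty locus list")
        if len(self.r) != len(self.loci) - 1:
            raise ValueError("need one recombination fraction per adjacent interval")
        if any(not 0.0 <= x <= 0.5 for x in self.r):
            raise ValueError("recombination fractions must be in [0, 0.5]")
        if self.gene not in self.loci:
            raise ValueError(f"gene {self.gene!r} not in loci")
        if not 0.0 <= self.phenotype_error <= 1.0:
            raise ValueError("phenotype_error must be in [0,1]")


@dataclass
class PopTruth:
    interval_recombinants: np.ndarray  # true recombinant gametes per interval
    n_gametes: int
    gametes: np.ndarray  # (n_gametes, n_loci) donor-allele indicator


def simulate_mapping_population(cfg: PopSimConfig) -> tuple[list[PlantRecord], PopTruth]:
    """Simulate F2 plants as pairs of independent no-interference gametes."""
    rng = np.random.default_rng(cfg.seed)
    n_loci = len(cfg.loci)
    n_gam = 2 * cfg.n_plants
    gene_k = cfg.loci.index(cfg.gene)

    if cfg.forced_recombinants is not None:
        # deterministic placement: parental gametes alternate phase; the
        # requested recombinant gametes go one-per-plant, first gamete
        start = (np.arange(n_gam) % 2).astype(bool)  # True = donor haplotype
        xo = np.zeros((n_gam, n_loci - 1), dtype=bool)
        used = 0
        for interval, count in cfg.forced_recombinants:
            for c in range(count):
                g = 2 * (used + c)
                if g >= n_gam:
                    raise ValueError("more forced recombinants than plants")
                xo[g, interval] = True
            used += count
    else:
        start = rng.random(n_gam) < 0.5
        xo = rng.random((n_gam, n_loci - 1)) < np.asarray(cfg.r)

    # allele at locus k = start XOR (parity of crossovers before k)
    parity = np.zeros((n_gam, n_loci), dtype=bool)
    parity[:, 1:] = np.cumsum(xo, axis=1) % 2
    gametes = start[:, None] ^ parity  # True = donor allele

    doses = gametes[0::2].astype(np.int8) + gametes[1::2].astype(np.int8)
    code = np.array(["B", "H", "A"])
    gene_geno = np.array(["rr", "Rr", "RR"])

    plants: list[PlantRecord] = []
    for p in range(cfg.n_plants):
        resistant = doses[p, gene_k] >= 1
        if cfg.phenotype_error > 0 and rng.random() < cfg.phenotype_error:
            resistant = not resistant
        raw = str(rng.choice(_R_ITS if resistant else _S_ITS))
        markers = {
            locus: str(code[doses[p, k]])
            for k, locus in enumerate(cfg.loci)
            if k != gene_k
        }
        plants.append(
            PlantRecord(
                id=f"F2_{p+1:04d}",
                marker_genotypes=markers,
                phenotype=classify_phenotype(raw),
                gene_genotype=str(gene_geno[doses[p, gene_k]]),
            )
        )
    truth = PopTruth(
        interval_recombinants=xo.sum(axis=0).astype(np.int64),
        n_gametes=n_gam,
        gametes=gametes,
    )
    return plants, truth


# ---------------------------------------------------------------------------
# amplicon pairs


_MAX_REJECTIONS = 10_000


def _expand_recognition(recognition: str, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(list(IUPAC[c]))) for c in recognition.upper())


def simulate_amplicon_pair(
    length: int,
    enzyme: RestrictionEnzyme,
    site_start: int | None,
    allele_effect: str = "destroys_site",
    indel_length: int = 0,
    seed: int = 0,
) -> tuple[str, str]:
    """Build an amplicon pair for a CAPS or InDel assay, with clean geometry.

    The background sequence is rejection-sampled to be free of incidental
    recognition sites (capped at 10,000 attempts). For ``destroys_site``
    the ref allele carries one concrete recognition instance at 1-based
    ``site_start`` and the alt allele a single-base change abolishing it;
    ``creates_site`` swaps the roles; ``indel`` deletes ``indel_length``
    bases from the alt allele; ``none`` returns an identical pair.
    """
    rng = np.random.default_rng(seed)
    L = len(enzyme.recognition)
    if allele_effect in ("destroys_site", "creates_site"):
        if site_start is None or not 1 <= site_start or site_start - 1 + L > length:
            raise ValueError(
                f"recognition site at {site_start} does not fit in {length} bp"
            )
    if allele_effect == "indel" and not 0 < indel_length < length:
        raise ValueError(f"indel length {indel_length} impossible for {length} bp amplicon")

    bases = np.array(list("ACGT"))
    for _ in range(_MAX_REJECTIONS):
        bg = "".join(rng.choice(bases, size=length))
        if allele_effect == "none":
            if not find_recognition_sites(bg, enzyme):
                return bg, bg
            continue
        if allele_effect == "indel":
            cut_at = (length - indel_length) // 2
            alt = bg[:cut_at] + bg[cut_at + indel_length :]
            if not find_recognition_sites(bg, enzyme) and not find_recognition_sites(alt, enzyme):
                return bg, alt
            continue
        s0 = site_start - 1
        concrete = _expand_recognition(enzyme.recognition, rng)
        with_site = bg[:s0] + concrete + bg[s0 + L :]
        # abolish by changing the first recognition base to a non-matching one
        allowed = [b for b in "ACGT" if b not in IUPAC[enzyme.recognition[0].upper()]]
        without_site = (
            with_site[:s0] + str(rng.choice(allowed)) + with_site[s0 + 1 :]
        )
        if find_recognition_sites(with_site, enzyme) == [site_start] and not find_recognition_sites(
            without_site, enzyme
        ):
            if allele_effect == "destroys_site":
                return with_site, without_site
            return without_site, with_site
    raise RuntimeError(
        f"could not sample a site-free background in {_MAX_REJECTIONS} attempts"
    )
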