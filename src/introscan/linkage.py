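"""Segregation tests, infection-type phenotyping, and genetic-map building
for a dominant rust-resistance locus in an F2/F3 mapping population.

The cross design is a coupling-phase F2: a resistant introgression line
(donor marker alleles, code A) crossed to a susceptible recipient (code B),
so every F2 plant is the union of two gametes drawn from a double
heterozygote and the donor allele travels with the resistance allele.
Map distances are tiny (< 1.1 cM), so cM is simply 100 x recombinant
gametes / total gametes with no mapping-function correction — Haldane or
Kosambi adjustments at these distances are far below rounding error.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

from scipy import stats

MARKER_CODES = ("A", "H", "B", "MISSING")
#: donor-allele dose of each marker / gene genotype code
_DOSE = {"A": 2, "H": 1, "B": 0, "RR": 2, "Rr": 1, "rr": 0}


def _round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# infection types


@dataclass(frozen=True)
class InfectionType:
    """A Stakman 0-4 rust infection type with its binary reading."""

    raw: str
    numeric_class: int
    binary: str  # "R" or "S"


def classify_phenotype(it: str, threshold: int = 2) -> InfectionType:
    """Parse a Stakman-scale string and call resistance.

    The dominant numeral decides the class: modifiers (";", "+", "-") are
    ignored and range strings such as "3-4" take the larger numeral. A pure
    fleck reaction (";" or "0;") is class 0. Resistant iff class <=
    ``threshold``. Unparseable strings raise — a bad score must never be
    silently treated as susceptible.
    """
    s = it.strip()
    if not s:
        raise ValueError("empty infection-type string")
    digits = re.findall(r"[0-9]", s)
    leftover = re.sub(r"[0-9;+\-–−]", "", s)
    if leftover:
        raise ValueError(f"unparseable infection type {it!r}")
    if digits:
        cls = max(int(d) for d in digits)
        if cls > 4:
            raise ValueError(f"infection type numeral out of 0-4 range in {it!r}")
    else:
        if set(s) != {";"}:
            raise ValueError(f"unparseable infection type {it!r}")
        cls = 0
    return InfectionType(raw=it, numeric_class=cls, binary="R" if cls <= threshold else "S")


# ---------------------------------------------------------------------------
# segregation chi-square


@dataclass(frozen=True)
class SegregationResult:
    n_R: int
    n_S: int
    ratio: tuple[float, float]
    chi2: float
    df: int
    p: float


def chi2_segregation(
    n_R: int, n_S: int, ratio: tuple[float, float] = (3, 1)
) -> SegregationResult:
    """Pearson chi-square of an observed R:S split against an expected ratio.

    No Yates continuity correction is applied; df = 1 for a two-class
    ratio. The upper-tail probability comes from the chi-square
    distribution.
    """
    total = n_R + n_S
    if total <= 0:
        raise ValueError("need at least one scored plant")
    w = ratio[0] + ratio[1]
    e_R = total * ratio[0] / w
    e_S = total * ratio[1] / w
    if e_R <= 0 or e_S <= 0:
        raise ValueError(f"nonpositive expected count under ratio {ratio}")
    chi2 = (n_R - e_R) ** 2 / e_R + (n_S - e_S) ** 2 / e_S
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(n_R=n_R, n_S=n_S, ratio=ratio, chi2=float(chi2), df=1, p=p)


# ---------------------------------------------------------------------------
# gene genotypes and recombinant gametes


def resolve_gene_genotype(
    progeny_phenotypes: Sequence[str], min_family_size: int = 12
) -> str:
    """Call the F2 plant's genotype at the resistance locus from an F3 family.

    All progeny resistant -> RR; all susceptible -> rr; both classes -> Rr.
    Families below ``min_family_size`` have too little power to separate RR
    from Rr (an Rr family of n shows no susceptible segregant with
    probability 0.75^n) and return UNKNOWN with a warning.
    """
    bad = [p for p in progeny_phenotypes if p not in ("R", "S")]
    if bad:
        raise ValueError(f"progeny phenotypes must be R or S, got {bad[:3]}")
    n = len(progeny_phenotypes)
    if n < min_family_size:
        warnings.warn(
            f"family of {n} below min_family_size={min_family_size}; genotype UNKNOWN",
            stacklevel=2,
        )
        return "UNKNOWN"
    n_S = sum(1 for p in progeny_phenotypes if p == "S")
    if n_S == 0:
        return "RR"
    if n_S == n:
        return "rr"
    return "Rr"


# the four gamete types of a coupling-phase double heterozygote, as
# (marker-locus donor dose, gene-locus donor dose, is_recombinant)
_GAMETES = [
    ((1, 1), 0),  # AR parental
    ((0, 0), 0),  # ar parental
    ((1, 0), 1),  # Ar recombinant
    ((0, 1), 1),  # aR recombinant
]


def _min_recombinants_for_doses(dose1: int, dose2: int) -> int:
    """Exhaustively minimize recombinant gametes over consistent pairs."""
    best = None
    for (g1, r1), (g2, r2) in combinations_with_replacement(_GAMETES, 2):
        if g1[0] + g2[0] == dose1 and g1[1] + g2[1] == dose2:
            n = r1 + r2
            best = n if best is None else min(best, n)
    if best is None:  # unreachable for doses in 0..2
        raise ValueError(f"inconsistent dose pair ({dose1}, {dose2})")
    return best


def count_recombinant_gametes(marker_code: str, gene_genotype: str) -> int | None:
    """Minimal recombinant gametes consistent with a two-locus F2 genotype.

    The plant is an unordered pair of gametes from {AR, ar, Ar, aR}; the
    returned count is the minimum number of recombinant gametes over all
    pairs reproducing the observed genotypes. The phase-ambiguous double
    heterozygote (H, Rr) resolves to 0 — at the sub-centimorgan distances
    involved, the double-recombinant reading is negligible. MISSING marker
    or UNKNOWN gene genotype returns None (excluded; caller tallies).
    """
    if marker_code == "MISSING" or gene_genotype == "UNKNOWN":
        return None
    if marker_code not in ("A", "H", "B"):
        raise ValueError(f"bad marker code {marker_code!r}")
    if gene_genotype not in ("RR", "Rr", "rr"):
        raise ValueError(f"bad gene genotype {gene_genotype!r}")
    return _min_recombinants_for_doses(_DOSE[marker_code], _DOSE[gene_genotype])


def map_distance(n_recombinant_gametes: int, n_total_gametes: int) -> float:
    """cM = 100 x recombinant fraction, rounded to 2 decimals half-up."""
    if n_total_gametes <= 0:
        raise ValueError("total gametes must be positive")
    if not 0 <= n_recombinant_gametes <= n_total_gametes:
        raise ValueError("recombinant count outside [0, total]")
    return _round_half_up(100.0 * n_recombinant_gametes / n_total_gametes, 2)


# ---------------------------------------------------------------------------
# plants and maps


@dataclass
class PlantRecord:
    id: str
    marker_genotypes: dict[str, str]  # marker -> A/H/B/MISSING
    phenotype: InfectionType | None = None
    gene_genotype: str = "UNKNOWN"  # RR/Rr/rr/UNKNOWN

    def is_inconsistent(self) -> bool:
        """Susceptible phenotype but a genotype carrying the dominant allele."""
        return (
            self.phenotype is not None
            and self.phenotype.binary == "S"
            and self.gene_genotype in ("RR", "Rr")
        )


@dataclass
class GeneticMap:
    loci: list[str]  # in map order
    positions_cM: list[float]  # cumulative, same order, rounded 2 d.p.
    interval_recombinants: list[int]  # per adjacent interval
    interval_totals: list[int]  # gametes scored per interval
    cosegregation_groups: list[list[str]]  # loci at identical cM


def _locus_dose(plant: PlantRecord, locus: str, gene: str | None) -> int | None:
    if gene is not None and locus == gene:
        if plant.gene_genotype == "UNKNOWN":
            return None
        return _DOSE[plant.gene_genotype]
    code = plant.marker_genotypes.get(locus, "MISSING")
    if code == "MISSING":
        return None
    if code not in ("A", "H", "B"):
        raise ValueError(f"bad marker code {code!r} at {locus} in plant {plant.id}")
    return _DOSE[code]


def build_genetic_map(
    population: Sequence[PlantRecord],
    loci: Sequence[str],
    gene: str | None = None,
    anchor: Mapping[str, float] | None = None,
) -> GeneticMap:
    """Build a genetic map over physically anchored loci.

    ``loci`` must already be in physical order (optionally checked against
    ``anchor`` positions); per adjacent interval, recombinant gametes are
    counted with the minimal-recombinant rule applied to donor-allele doses
    at the two loci, over plants with both loci scored. Intervals with zero
    recombinants collapse their flanking loci into one co-segregation
    group.
    """
    if not population:
        raise ValueError("empty population")
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    if anchor is not None:
        pos = [anchor[l] for l in loci if l in anchor]
        if pos != sorted(pos):
            raise ValueError("loci are not in physical-anchor order")
    for locus in loci:
        if not any(_locus_dose(p, locus, gene) is not None for p in population):
            raise ValueError(f"locus {locus!r} is unscored in every plant")

    interval_rec: list[int] = []
    interval_tot: list[int] = []
    for la, lb in zip(loci[:-1], loci[1:]):
        rec = tot = 0
        for plant in population:
            da = _locus_dose(plant, la, gene)
            db = _locus_dose(plant, lb, gene)
            if da is None or db is None:
                continue
            rec += _min_recombinants_for_doses(da, db)
            tot += 2
        if tot == 0:
            raise ValueError(f"no plant scored at both {la!r} and {lb!r}")
        interval_rec.append(rec)
        interval_tot.append(tot)

    positions = [0.0]
    for rec, tot in zip(interval_rec, interval_tot):
        positions.append(_round_half_up(positions[-1] + 100.0 * rec / tot, 2))
    positions = [_round_half_up(p, 2) for p in positions]

    groups: list[list[str]] = [[loci[0]]]
    for locus, rec in zip(loci[1:], interval_rec):
        if rec == 0:
            groups[-1].append(locus)
        else:
            groups.append([locus])

    return GeneticMap(
        loci=list(loci),
        positions_cM=positions,
        interval_recombinants=interval_rec,
        interval_totals=interval_tot,
        cosegregation_groups=groups,
    )


# ---------------------------------------------------------------------------
# marker-panel validation


@dataclass
class MarkerPanelSummary:
    per_marker: dict[str, dict[str, tuple[int, int, float]]]
    # marker -> group -> (n_amplifying, n_total, percent to 1 d.p.)
    n_haplotype_identical: int
    identical_accessions: list[str]


def validate_marker_panel(
    calls: Mapping[str, Mapping[str, str | None]],
    reference_haplotype: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> MarkerPanelSummary:
    """Summarize a marker screen of a germplasm collection.

    ``calls`` maps accession -> marker -> allele string, with None (or a
    missing key) meaning no amplification. Amplification percentages are
    per species group (single group "all" when none given), one decimal,
    half-up. An accession matches the reference haplotype only if it
    amplifies and agrees at every reference marker.
    """
    markers = list(reference_haplotype)
    per_marker: dict[str, dict[str, tuple[int, int, float]]] = {}
    grp = groups or {acc: "all" for acc in calls}
    group_names = sorted(set(grp.values()))
    for m in markers:
        per_marker[m] = {}
        for g in group_names:
            accs = [a for a in calls if grp.get(a, "all") == g]
            n_amp = sum(1 for a in accs if calls[a].get(m) is not None)
            pct = _round_half_up(100.0 * n_amp / len(accs), 1) if accs else 0.0
            per_marker[m][g] = (n_amp, len(accs), pct)
    identical = [
        a
        for a in calls
        if all(calls[a].get(m) is not None and calls[a][m] == reference_haplotype[m] for m in markers)
    ]
    return MarkerPanelSummary(
        per_marker=per_marker,
        n_haplotype_identical=len(identical),
        identical_accessions=identical,
    )


def read_population_tsv(path, loci: Sequence[str] | None = None) -> list[PlantRecord]:
    """Read a mapping-population table.

    Columns: ``id``, one column per marker (codes A/H/B/NA), an
    ``infection_type`` column with raw Stakman strings, and an optional
    ``gene_genotype`` column (RR/Rr/rr/UNKNOWN) from progeny tests. When
    ``loci`` is given only those marker columns are read.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError(f"population TSV {path} lacks an 'id' column")
    special = {"id", "infection_type", "gene_genotype"}
    markers = [c for c in df.columns if c not in special]
    if loci is not None:
        missing = [l for l in loci if l not in markers]
        if missing:
            raise ValueError(f"loci {missing} absent from {path}")
        markers = [l for l in loci if l in markers]
    plants: list[PlantRecord] = []
    for row in df.to_dict("records"):
        genos = {}
        for m in markers:
            v = row[m].strip()
            genos[m] = "MISSING" if v in ("NA", "", ".") else v
        pheno = None
        if "infection_type" in df.columns and row["infection_type"].strip():
            pheno = classify_phenotype(row["infection_type"])
        gg = row.get("gene_genotype", "").strip() or "UNKNOWN"
        if gg not in ("RR", "Rr", "rr", "UNKNOWN"):
            raise ValueError(f"bad gene_genotype {gg!r} for plant {row['id']}")
        plants.append(
            PlantRecord(id=row["id"], marker_genotypes=genos, phenotype=pheno, gene_genotype=gg)
        )
    return plants


def write_population_tsv(population: Sequence[PlantRecord], path) -> None:
    markers: list[str] = []
    for p in population:
        for m in p.marker_genotypes:
            if m not in markers:
                markers.append(m)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(markers) + "\tinfection_type\tgene_genotype\n")
        for p in population:
            codes = [
                "NA" if p.marker_genotypes.get(m, "MISSING") == "MISSING" else p.marker_genotypes[m]
                for m in markers
            ]
            it = p.phenotype.raw if p.phenotype is not None else ""
            fh.write(f"{p.id}\t" + "\t".join(codes) + f"\t{it}\t{p.gene_genotype}\n")


def write_map_text(gmap: GeneticMap, path) -> None:
    """MapChart-style plain text: locus and cumulative cM per line."""
    with open(path, "w") as fh:
        for locus, pos in zip(gmap.loci, gmap.positions_cM):
            fh.write(f"{locus}\t{pos:.2f}\n")
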