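"""Species-diagnostic SNP classification and introgressed-segment detection.

The scan answers two questions about a query wheat line genotyped against a
multi-species panel: (1) at which SNPs does the query carry an allele that is
fixed in the candidate donor species group and absent from every polyploid
wheat reference ("donor-diagnostic" SNPs), and (2) over which contiguous
physical interval do those query-shared diagnostic SNPs run, i.e. where is
the alien segment and where does the translocation breakpoint lie.

Classification rules
--------------------
For each biallelic site, looking only at the non-reference (alt) allele:

* DONOR_DIAGNOSTIC — alt present in ALL non-missing donor-candidate
  accessions and absent from ALL non-missing polyploid references, with at
  least one non-missing call in each group and per-group missing fractions
  within the policy limit.
* SHARED_WHEAT — alt present in at least one polyploid reference (a normal
  wheat polymorphism).
* QUERY_RARE — the query carries the alt allele, no reference does, but the
  donor condition fails (a rare polymorphism private to the query relative
  to polyploid wheat).
* UNINFORMATIVE — everything else (including monomorphic columns).

The categories are mutually exclusive and exhaustive.

Breakpoint bracketing
---------------------
The segment is the longest run of query-shared diagnostic SNPs satisfying
gap and windowed-density constraints. Its last supporting SNP is the lower
bracket of the translocation breakpoint; the upper bracket is the first SNP
beyond the run at which the query itself shows wheat-type evidence — a
shared-wheat SNP whose alt allele the query carries. Background wheat
polymorphism also occurs *inside* an alien segment (the panel is polymorphic
genome-wide), so a shared-wheat site as such says nothing about where the
query's donor chromatin ends; the query's own genotype there does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .panel_io import (
    HET,
    HOM_ALT,
    MISSING,
    GenotypeMatrix,
    Group,
    PanelAccession,
    VariantSite,
    validate_panel,
)


class SiteCategory(str, Enum):
    DONOR_DIAGNOSTIC = "DONOR_DIAGNOSTIC"
    QUERY_RARE = "QUERY_RARE"
    SHARED_WHEAT = "SHARED_WHEAT"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class ClassificationPolicy:
    """How genotype calls enter the presence/absence tests.

    het_carries
        If True (default), a heterozygous call counts as carrying the alt
        allele. RNA-seq genotypes of a polyploid make hom/het dosage
        unreliable, so presence is the robust reading.
    max_missing_fraction
        Maximum tolerated fraction of MISSING calls in the donor and
        reference groups for a site to remain eligible for
        DONOR_DIAGNOSTIC status.
    """

    het_carries: bool = True
    max_missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError(
                f"max_missing_fraction must be in [0,1], got {self.max_missing_fraction}"
            )


@dataclass(frozen=True)
class SiteClassification:
    site: VariantSite
    category: SiteCategory
    query_carries_donor_allele: bool
    n_missing: int


@dataclass
class IntrogressionCall:
    """A located alien segment with its breakpoint bracket.

    Coordinates are 1-based bp. ``breakpoint_lo`` equals ``segment_end``
    (the last supporting SNP); ``breakpoint_hi`` is the first wheat-type
    query SNP beyond the run, or the chromosome-end sentinel
    (chrom_length + 1) when no such SNP exists.
    """

    chrom: str
    segment_start: int
    segment_end: int
    breakpoint_lo: int
    breakpoint_hi: int
    n_support: int
    density_profile: list[tuple[int, int, int, int]] = field(default_factory=list)
    # density_profile rows: (window_start, window_end, n_diagnostic, n_classified)

    def __post_init__(self) -> None:
        if not self.segment_start <= self.segment_end < self.breakpoint_hi:
            raise ValueError(
                f"invalid call: start={self.segment_start} end={self.segment_end} "
                f"hi={self.breakpoint_hi}"
            )


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the segment scan (all in bp unless noted).

    Defaults are robust on dense RNA-seq-derived SNP panels: a real alien
    segment yields diagnostic SNPs every few tens of kb, so a 10 Mb gap
    ceiling, 1 Mb density windows at >=50% diagnostic, and 20 supporting
    SNPs minimum separate signal from scattered misclassified sites.
    """

    min_support: int = 20
    window_bp: int = 1_000_000
    min_window_fraction: float = 0.5
    max_gap_bp: int = 10_000_000
    chrom_length: int | None = None


def _carries_alt(calls: np.ndarray, het_carries: bool) -> np.ndarray:
    """Boolean: does each call carry >=1 alt allele under the het policy."""
    if het_carries:
        return (calls == HOM_ALT) | (calls == HET)
    return calls == HOM_ALT


def classify_sites(
    G: GenotypeMatrix,
    panel: Sequence[PanelAccession],
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[SiteClassification]:
    """Assign every site to exactly one diagnostic category."""
    validate_panel(panel)
    by_id = {a.id: a for a in panel}
    missing_from_matrix = [a.id for a in panel if a.id not in G.accessions]
    if missing_from_matrix:
        raise ValueError(f"panel accessions absent from matrix: {missing_from_matrix}")

    donor_idx = [G.accession_index(a.id) for a in panel if a.group is Group.DONOR_CANDIDATE]
    ref_idx = [G.accession_index(a.id) for a in panel if a.group is Group.POLYPLOID_REFERENCE]
    query_idx = next(G.accession_index(a.id) for a in panel if a.group is Group.QUERY)

    calls = G.calls
    carries = _carries_alt(calls, policy.het_carries)
    miss = calls == MISSING

    donors_c = carries[:, donor_idx]
    donors_m = miss[:, donor_idx]
    refs_c = carries[:, ref_idx]
    refs_m = miss[:, ref_idx]

    donor_nonmiss = (~donors_m).sum(axis=1)
    ref_nonmiss = (~refs_m).sum(axis=1)
    donor_missfrac = donors_m.mean(axis=1)
    ref_missfrac = refs_m.mean(axis=1)

    alt_in_all_donors = (donors_c | donors_m).all(axis=1) & (donor_nonmiss >= 1)
    alt_in_any_ref = refs_c.any(axis=1)

    diagnostic = (
        alt_in_all_donors
        & ~alt_in_any_ref
        & (ref_nonmiss >= 1)
        & (donor_missfrac <= policy.max_missing_fraction)
        & (ref_missfrac <= policy.max_missing_fraction)
    )
    query_alt = carries[:, query_idx]
    shared = ~diagnostic & alt_in_any_ref
    rare = ~diagnostic & ~shared & query_alt & ~alt_in_any_ref

    n_missing_per_site = miss[:, donor_idx + ref_idx + [query_idx]].sum(axis=1)

    out: list[SiteClassification] = []
    for i, site in enumerate(G.sites):
        if diagnostic[i]:
            cat = SiteCategory.DONOR_DIAGNOSTIC
        elif shared[i]:
            cat = SiteCategory.SHARED_WHEAT
        elif rare[i]:
            cat = SiteCategory.QUERY_RARE
        else:
            cat = SiteCategory.UNINFORMATIVE
        out.append(
            SiteClassification(
                site=site,
                category=cat,
                query_carries_donor_allele=bool(query_alt[i]),
                n_missing=int(n_missing_per_site[i]),
            )
        )
    return out


def _window_profile(
    positions: np.ndarray,
    supporting: np.ndarray,
    start: int,
    end: int,
    window_bp: int,
) -> list[tuple[int, int, int, int]]:
    """Absolute window_bp tiles intersecting [start, end], with counts.

    Tiles are anchored at coordinate 1 (tile m covers
    [(m-1)*window_bp + 1, m*window_bp]), so a window's diagnostic fraction
    does not depend on which candidate run is being examined.
    """
    profile = []
    first = (start - 1) // window_bp
    last = (end - 1) // window_bp
    for m in range(first, last + 1):
        w = m * window_bp + 1
        w_end = (m + 1) * window_bp
        in_w = (positions >= w) & (positions <= w_end)
        profile.append((w, w_end, int(supporting[in_w].sum()), int(in_w.sum())))
    return profile


def _bad_tiles(
    positions: np.ndarray,
    supporting: np.ndarray,
    window_bp: int,
    min_fraction: float,
) -> list[tuple[int, int]]:
    """Absolute tiles whose diagnostic fraction falls below min_fraction.

    Tiles containing no classified site pass vacuously.
    """
    tiles = (positions - 1) // window_bp
    out = []
    for m in np.unique(tiles):
        in_w = tiles == m
        n_all = int(in_w.sum())
        n_diag = int(supporting[in_w].sum())
        if n_all > 0 and n_diag / n_all < min_fraction:
            out.append((int(m) * window_bp + 1, (int(m) + 1) * window_bp))
    return out


def run_qualifies(
    positions: np.ndarray,
    supporting: np.ndarray,
    start: int,
    end: int,
    params: DetectionParams,
) -> bool:
    """Does the support run spanning [start, end] satisfy all predicates?

    Predicates: start/end are supporting sites; consecutive supports are
    <= max_gap_bp apart; n_support >= min_support; and every absolute
    window_bp tile fully contained in [start, end] that holds >= 1
    classified site is at least min_window_fraction diagnostic.
    """
    in_run = (positions >= start) & (positions <= end)
    sup = positions[in_run & supporting]
    if sup.size < params.min_support or sup[0] != start or sup[-1] != end:
        return False
    if sup.size > 1 and int(np.diff(sup).max()) > params.max_gap_bp:
        return False
    for a, b in _bad_tiles(
        positions[in_run], supporting[in_run], params.window_bp, params.min_window_fraction
    ):
        if start <= a and b <= end:
            return False
    return True


def detect_segment(
    classified: Sequence[SiteClassification],
    params: DetectionParams = DetectionParams(),
) -> IntrogressionCall | None:
    """Locate the alien segment on one chromosome, or return None.

    A candidate run is a contiguous block of query-shared DONOR_DIAGNOSTIC
    SNPs with consecutive supports <= max_gap_bp apart in which every
    absolute window_bp tile fully contained in the run (counting all
    classified SNPs it holds) is at least min_window_fraction diagnostic.
    The longest qualifying run (bp span; ties broken by larger n_support,
    then more distal start) with n_support >= min_support is reported.
    """
    if not classified:
        return None
    chroms = {c.site.chrom for c in classified}
    if len(chroms) != 1:
        raise ValueError(f"detect_segment handles one chromosome at a time, got {chroms}")
    chrom = chroms.pop()

    positions = np.array([c.site.pos for c in classified], dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("classified sites must be sorted by position")
    supporting = np.array(
        [
            c.category is SiteCategory.DONOR_DIAGNOSTIC and c.query_carries_donor_allele
            for c in classified
        ],
        dtype=bool,
    )
    sup_pos = positions[supporting]
    if sup_pos.size == 0:
        return None

    # split supports into maximal gap-bounded blocks, then search sub-runs
    gap_breaks = np.nonzero(np.diff(sup_pos) > params.max_gap_bp)[0]
    blocks = np.split(sup_pos, gap_breaks + 1)

    bad = _bad_tiles(positions, supporting, params.window_bp, params.min_window_fraction)

    best: tuple[int, int, int] | None = None  # (bp span, n_support, start) maximized
    best_run: tuple[int, int] | None = None
    for block in blocks:
        if block.size < params.min_support:
            continue
        span_lo, span_hi = int(block[0]), int(block[-1])
        # only tiles a run inside this block could fully contain matter;
        # any qualifying run lies inside one maximal interval between
        # consecutive such tiles, so checking those snaps is exact
        rel = [(a, b) for a, b in bad if a >= span_lo and b <= span_hi]
        lo_bounds = [span_lo] + [a + 1 for a, _ in rel]
        hi_bounds = [b - 1 for _, b in rel] + [span_hi]
        for lo, hi in zip(lo_bounds, hi_bounds):
            sub = block[(block >= lo) & (block <= hi)]
            if sub.size < params.min_support:
                continue
            s, e = int(sub[0]), int(sub[-1])
            key = (e - s, int(sub.size), s)
            if best is None or key > best:
                best = key
                best_run = (s, e)

    if best_run is None:
        return None
    seg_start, seg_end = best_run
    n_support = int(((sup_pos >= seg_start) & (sup_pos <= seg_end)).sum())

    # upper bracket: first wheat-type query SNP beyond the run
    wheat_type = np.array(
        [
            c.category is SiteCategory.SHARED_WHEAT
            and c.query_carries_donor_allele  # query carries the alt (wheat) allele
            for c in classified
        ],
        dtype=bool,
    )
    beyond = positions[wheat_type & (positions > seg_end)]
    if beyond.size:
        breakpoint_hi = int(beyond[0])
    else:
        sentinel = params.chrom_length if params.chrom_length is not None else int(positions[-1])
        breakpoint_hi = max(sentinel, seg_end) + 1

    return IntrogressionCall(
        chrom=chrom,
        segment_start=seg_start,
        segment_end=seg_end,
        breakpoint_lo=seg_end,
        breakpoint_hi=breakpoint_hi,
        n_support=n_support,
        density_profile=_window_profile(
            positions, supporting, seg_start, seg_end, params.window_bp
        ),
    )


def restrict_to_region(
    G: GenotypeMatrix, chrom: str, start_bp: int, end_bp: int
) -> GenotypeMatrix:
    """Subset a matrix to sites with start_bp <= pos <= end_bp on chrom."""
    if start_bp > end_bp:
        raise ValueError(f"start {start_bp} > end {end_bp}")
    if chrom not in {s.chrom for s in G.sites}:
        raise ValueError(f"unknown chromosome {chrom!r}")
    keep = [
        i
        for i, s in enumerate(G.sites)
        if s.chrom == chrom and start_bp <= s.pos <= end_bp
    ]
    return GenotypeMatrix(
        sites=[G.sites[i] for i in keep],
        accessions=list(G.accessions),
        calls=G.calls[keep, :] if keep else np.empty((0, G.n_accessions), dtype=np.int8),
    )


def write_classification_tsv(
    classified: Sequence[SiteClassification], path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcategory\tquery_carries_donor_allele\tn_missing\n")
        for c in classified:
            s = c.site
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{c.category.value}\t{int(c.query_carries_donor_allele)}\t{c.n_missing}\n"
            )


def write_density_tsv(call: IntrogressionCall, path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\twindow_end\tn_diagnostic\tn_classified\n")
        for w in call.density_profile:
            fh.write("\t".join(str(x) for x in w) + "\n")
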