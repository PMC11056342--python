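"""Readers and writers for the formats the pipeline touches.

This module is deliberately science-free: it maps files to in-memory
containers (and back) and validates structure, leaving every biological
decision (het handling, classification, thresholds) to downstream modules.

Coordinates are 1-based inclusive internally (the VCF convention); the BED
writer converts to 0-based half-open on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

# integer genotype codes used throughout the package
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: mapping between the TSV dialect's column codes and internal codes
_TSV_CODE = {"0": HOM_REF, "1": HET, "2": HOM_ALT, "NA": MISSING}
_TSV_CODE_INV = {v: k for k, v in _TSV_CODE.items()}


class Group(str, Enum):
    """Role of a panel accession in the origin analysis."""

    DONOR_CANDIDATE = "DONOR_CANDIDATE"
    POLYPLOID_REFERENCE = "POLYPLOID_REFERENCE"
    QUERY = "QUERY"


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP at a 1-based physical coordinate."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Site x accession biallelic genotype calls.

    ``calls[i, j]`` is the code of accession ``j`` at site ``i``, one of
    HOM_REF (0), HET (1), HOM_ALT (2) or MISSING (-1). Sites are strictly
    sorted by (chrom, pos) with no duplicates.
    """

    sites: list[VariantSite]
    accessions: list[str]
    calls: np.ndarray  # shape (n_sites, n_accessions), dtype int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.accessions)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.accessions)} accessions"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        for s in self.sites:
            key = (s.chrom, s.pos)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)
            if prev is not None and prev[0] == s.chrom and prev[1] >= s.pos:
                raise ValueError(f"sites not sorted within {s.chrom} at pos {s.pos}")
            prev = key

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def accession_index(self, name: str) -> int:
        try:
            return self.accessions.index(name)
        except ValueError:
            raise KeyError(f"unknown accession {name!r}") from None

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out


@dataclass(frozen=True)
class PanelAccession:
    id: str
    species: str
    group: Group


def validate_panel(panel: Sequence[PanelAccession]) -> None:
    """Check the one-query / >=1-donor / >=1-reference contract."""
    n_query = sum(1 for a in panel if a.group is Group.QUERY)
    if n_query != 1:
        raise ValueError(f"panel must have exactly one QUERY accession, got {n_query}")
    if not any(a.group is Group.DONOR_CANDIDATE for a in panel):
        raise ValueError("panel needs at least one DONOR_CANDIDATE accession")
    if not any(a.group is Group.POLYPLOID_REFERENCE for a in panel):
        raise ValueError("panel needs at least one POLYPLOID_REFERENCE accession")


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype table from VCF or the package's TSV dialect.

    VCF records that are not biallelic SNPs (indels, multi-allelic sites)
    are skipped; the skip count is logged. Only the GT field is consulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} declares no samples")

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if (
            len(var.ALT) != 1
            or len(var.REF) != 1
            or len(var.ALT[0]) != 1
            or var.REF not in VALID_BASES
            or var.ALT[0] not in VALID_BASES
        ):
            n_skipped += 1
            continue
        sites.append(VariantSite(var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.gt_types):
            row[j] = {0: HOM_REF, 1: HET, 3: HOM_ALT}.get(int(g), MISSING)
        rows.append(row)
    if n_skipped:
        log.info("skipped %d non-SNP records in %s", n_skipped, path)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    mat = GenotypeMatrix(sites=sites, accessions=samples, calls=calls)
    mat.n_skipped = n_skipped  # type: ignore[attr-defined]
    return mat


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"malformed TSV header in {path}: first columns must be {required}, "
            f"got {list(df.columns[:4])}"
        )
    accessions = list(df.columns[4:])
    if not accessions:
        raise ValueError(f"genotype TSV {path} has no accession columns")
    sites = [
        VariantSite(r.chrom, int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
    calls = np.empty((len(sites), len(accessions)), dtype=np.int8)
    for j, acc in enumerate(accessions):
        try:
            calls[:, j] = [_TSV_CODE[v] for v in df[acc]]
        except KeyError as exc:
            raise ValueError(
                f"invalid genotype code {exc.args[0]!r} in column {acc!r} of {path}"
            ) from None
    return GenotypeMatrix(sites=sites, accessions=accessions, calls=calls)


def write_genotype_tsv(mat: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV genotype dialect (codes 0/1/2/NA, 1-based positions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *mat.accessions]) + "\n")
        for i, s in enumerate(mat.sites):
            codes = [_TSV_CODE_INV[int(c)] for c in mat.calls[i]]
            fh.write("\t".join([s.chrom, str(s.pos), s.ref_allele, s.alt_allele, *codes]) + "\n")


def write_genotype_vcf(mat: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in mat.chroms():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(mat.accessions)
            + "\n"
        )
        for i, s in enumerate(mat.sites):
            cols = [s.chrom, str(s.pos), ".", s.ref_allele, s.alt_allele, ".", ".", ".", "GT"]
            cols += [gt[int(c)] for c in mat.calls[i]]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# panel metadata


def read_panel_metadata(path: str | Path) -> list[PanelAccession]:
    """Read the panel TSV (columns: id, species, group).

    Group labels are parsed case-insensitively. Duplicate ids and more than
    one QUERY row are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "species", "group"):
        if col not in df.columns:
            raise ValueError(f"panel TSV {path} lacks required column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate accession id {dup!r} in {path}")
    out: list[PanelAccession] = []
    for r in df.itertuples(index=False):
        try:
            group = Group[str(r.group).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown group {r.group!r} for accession {r.id!r}; "
                f"expected one of {[g.name for g in Group]}"
            ) from None
        out.append(PanelAccession(id=r.id, species=r.species, group=group))
    if sum(1 for a in out if a.group is Group.QUERY) > 1:
        raise ValueError(f"more than one QUERY accession in {path}")
    return out


def write_panel_metadata(panel: Sequence[PanelAccession], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tgroup\n")
        for a in panel:
            fh.write(f"{a.id}\t{a.species}\t{a.group.name}\n")


# ---------------------------------------------------------------------------
# BED export


def write_segment_bed(call, path: str | Path) -> None:
    """Write an introgression call as one BED line (0-based half-open).

    ``call`` may be None / an empty call, in which case an empty file is
    written.
    """
    with open(path, "w") as fh:
        if call is None:
            return
        fh.write(f"{call.chrom}\t{call.segment_start - 1}\t{call.segment_end}\n")
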