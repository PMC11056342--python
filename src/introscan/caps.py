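"""In-silico evaluation of CAPS and InDel PCR markers.

A CAPS (Cleaved Amplified Polymorphic Sequence) marker distinguishes two
alleles of a PCR amplicon by presence/absence of a restriction-enzyme
recognition site: digesting the site-bearing allele yields two (or more)
bands where the other allele stays intact. This module scans degenerate
IUPAC recognition patterns, predicts digestion fragment lengths for a
linear amplicon, and judges whether the banding patterns of the two alleles
are distinguishable on a gel.

An InDel marker is simpler: the alleles differ in amplicon length, and the
verdict is a pure length comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II enzyme: IUPAC recognition string and top-strand cut offset.

    ``cut_offset`` counts bases after the recognition start on the top
    strand; AvaI (C^YCGRG) has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters {bad} in recognition of {self.name}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside recognition of {self.name}"
            )

    @property
    def is_palindromic(self) -> bool:
        """Palindromic under IUPAC: reverse complement equals the pattern."""
        return reverse_complement(self.recognition.upper()) == self.recognition.upper()


AVAI = RestrictionEnzyme(name="AvaI", recognition="CYCGRG", cut_offset=1)


@dataclass
class CAPSAssay:
    marker: str
    ref_amplicon: str
    alt_amplicon: str
    enzyme: RestrictionEnzyme
    fragments_ref: list[int]
    fragments_alt: list[int]
    diagnostic: bool
    min_resolvable_diff: int


def _check_seq(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return s


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern.upper()))


def _find_matches(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition matches as (0-based top-strand start, strand).

    Overlapping matches are reported. Palindromic patterns need only the
    top strand; others are additionally matched on the reverse complement
    with positions mapped back to top-strand coordinates.
    """
    s = _check_seq(seq)
    rx = _iupac_regex(enzyme.recognition)
    L = len(enzyme.recognition)
    # lookahead so overlapping occurrences are all reported
    hits = [(m.start(), "+") for m in re.finditer(f"(?=({rx.pattern}))", s)]
    if not enzyme.is_palindromic:
        rc = reverse_complement(s)
        for m in re.finditer(f"(?=({rx.pattern}))", rc):
            top_start = len(s) - m.start() - L
            hits.append((top_start, "-"))
    return sorted(set(hits))


def find_recognition_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based top-strand start positions of all recognition matches."""
    return sorted({start + 1 for start, _ in _find_matches(seq, enzyme)})


def digest(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths (5'->3') of a linear digest; sums to len(seq).

    The top-strand cut falls after ``start + cut_offset`` bases; matches on
    the bottom strand cut after ``start + len(recognition) - cut_offset``
    bases (the mirrored offset). Cuts at identical positions, or at the
    molecule ends, are deduplicated/ignored. No sites -> one full-length
    fragment.
    """
    s = _check_seq(seq)
    cuts = set()
    L = len(enzyme.recognition)
    for start, strand in _find_matches(s, enzyme):
        cut = start + (enzyme.cut_offset if strand == "+" else L - enzyme.cut_offset)
        if 0 < cut < len(s):
            cuts.add(cut)
    bounds = [0, *sorted(cuts), len(s)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def _visible(fragments: Sequence[int], min_resolvable_diff: int) -> list[int]:
    """Bands a gel can show: fragments at least min_resolvable_diff long."""
    return sorted(f for f in fragments if f >= min_resolvable_diff)


def _patterns_distinguishable(
    frags_a: Sequence[int], frags_b: Sequence[int], min_resolvable_diff: int
) -> bool:
    va = _visible(frags_a, min_resolvable_diff)
    vb = _visible(frags_b, min_resolvable_diff)
    if len(va) != len(vb):
        return True
    return any(abs(a - b) >= min_resolvable_diff for a, b in zip(va, vb))


def evaluate_caps_assay(
    ref_amplicon: str,
    alt_amplicon: str,
    enzyme: RestrictionEnzyme,
    min_resolvable_diff: int = 20,
    marker: str = "",
) -> CAPSAssay:
    """Digest both alleles and judge whether a gel separates them.

    The verdict treats fragments shorter than ``min_resolvable_diff`` as
    invisible (they run off or cannot be resolved) and requires either a
    different number of visible bands or at least one band pair differing
    by ``min_resolvable_diff`` bp.
    """
    fr = digest(ref_amplicon, enzyme)
    fa = digest(alt_amplicon, enzyme)
    return CAPSAssay(
        marker=marker,
        ref_amplicon=ref_amplicon.upper(),
        alt_amplicon=alt_amplicon.upper(),
        enzyme=enzyme,
        fragments_ref=sorted(fr),
        fragments_alt=sorted(fa),
        diagnostic=_patterns_distinguishable(fr, fa, min_resolvable_diff),
        min_resolvable_diff=min_resolvable_diff,
    )


def _discrimination_score(assay: CAPSAssay) -> float:
    """Smallest band difference a gel must resolve to tell the alleles apart.

    Both visible patterns are padded with zero-length pseudo-bands to equal
    count and compared position-wise; the score is the minimum nonzero
    pairwise difference (larger is easier to score on a gel).
    """
    va = _visible(assay.fragments_ref, assay.min_resolvable_diff)
    vb = _visible(assay.fragments_alt, assay.min_resolvable_diff)
    n = max(len(va), len(vb))
    va = [0] * (n - len(va)) + va
    vb = [0] * (n - len(vb)) + vb
    diffs = [abs(a - b) for a, b in zip(va, vb) if a != b]
    return float(min(diffs)) if diffs else 0.0


def propose_enzymes(
    ref_amplicon: str,
    alt_amplicon: str,
    snp_position: int,
    enzyme_table: Sequence[RestrictionEnzyme],
    min_resolvable_diff: int = 20,
) -> list[tuple[RestrictionEnzyme, float]]:
    """Rank enzymes able to turn a SNP into a CAPS assay.

    Candidates must have a recognition match (in either allele) whose
    window covers ``snp_position`` (1-based) and must produce
    distinguishable digestion patterns; they are ranked by descending
    discrimination score.
    """
    if not enzyme_table:
        raise ValueError("empty enzyme table")
    out: list[tuple[RestrictionEnzyme, float]] = []
    for enz in enzyme_table:
        L = len(enz.recognition)
        overlaps = any(
            start + 1 <= snp_position <= start + L
            for seq in (ref_amplicon, alt_amplicon)
            for start, _ in _find_matches(seq, enz)
        )
        if not overlaps:
            continue
        assay = evaluate_caps_assay(
            ref_amplicon, alt_amplicon, enz, min_resolvable_diff, marker=enz.name
        )
        if assay.diagnostic:
            out.append((enz, _discrimination_score(assay)))
    return sorted(out, key=lambda t: (-t[1], t[0].name))


@dataclass
class InDelVerdict:
    len_ref: int
    len_alt: int
    diagnostic: bool


def evaluate_indel_marker(
    ref_amplicon: str, alt_amplicon: str, min_resolvable_diff: int = 20
) -> InDelVerdict:
    """Length-polymorphism verdict: resolvable iff sizes differ enough."""
    if not ref_amplicon or not alt_amplicon:
        raise ValueError("amplicons must be nonempty")
    lr, la = len(ref_amplicon), len(alt_amplicon)
    return InDelVerdict(len_ref=lr, len_alt=la, diagnostic=abs(lr - la) >= min_resolvable_diff)


def load_enzyme_table(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Load enzymes from a TSV (name, recognition, cut_offset).

    With no path, the small table shipped with the package (seeded with
    AvaI and a few common six-cutters) is used.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "enzymes.tsv"
    enzymes = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["name", "recognition", "cut_offset"]:
            raise ValueError(f"bad enzyme table header in {path}: {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, recog, off = line.strip().split("\t")[:3]
            enzymes.append(RestrictionEnzyme(name=name, recognition=recog, cut_offset=int(off)))
    return enzymes


def write_assay_tsv(assays: Sequence[CAPSAssay], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tenzyme\tfragments_ref\tfragments_alt\tdiagnostic\n")
        for a in assays:
            fh.write(
                f"{a.marker}\t{a.enzyme.name}\t"
                f"{','.join(map(str, a.fragments_ref))}\t"
                f"{','.join(map(str, a.fragments_alt))}\t"
                f"{int(a.diagnostic)}\n"
            )
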