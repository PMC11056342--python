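import numpy as np
import pytest

from introscan.panel_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Group,
    PanelAccession,
    VariantSite,
)
from introscan.scan import (
    ClassificationPolicy,
    DetectionParams,
    SiteCategory,
    SiteClassification,
    classify_sites,
    detect_segment,
    restrict_to_region,
)

from conftest import matrix_from_columns


def small_panel(n_donor=2, n_ref=3):
    return (
        [PanelAccession(f"d{i}", "donor", Group.DONOR_CANDIDATE) for i in range(n_donor)]
        + [PanelAccession(f"w{i}", "wheat", Group.POLYPLOID_REFERENCE) for i in range(n_ref)]
        + [PanelAccession("q", "query", Group.QUERY)]
    )


def classify_one(column, policy=ClassificationPolicy(), n_donor=2, n_ref=3):
    """Classify a single site given calls ordered donors, refs, query."""
    accs = [f"d{i}" for i in range(n_donor)] + [f"w{i}" for i in range(n_ref)] + ["q"]
    mat = matrix_from_columns([100], [[c] for c in column], accs)
    return classify_sites(mat, small_panel(n_donor, n_ref), policy)[0]


class TestClassifySites:
    def test_donor_diagnostic_shared_with_query(self):
        c = classify_one([HOM_ALT, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT])
        assert c.category is SiteCategory.DONOR_DIAGNOSTIC
        assert c.query_carries_donor_allele

    def test_monomorphic_uninformative(self):
        c = classify_one([HOM_REF] * 6)
        assert c.category is SiteCategory.UNINFORMATIVE
        assert not c.query_carries_donor_allele

    def test_shared_wheat_trumps_rare(self):
        # alt in one reference: wheat polymorphism even though query carries it
        c = classify_one([HOM_REF, HOM_REF, HOM_ALT, HOM_REF, HOM_REF, HOM_ALT])
        assert c.category is SiteCategory.SHARED_WHEAT

    def test_query_rare(self):
        c = classify_one([HOM_REF, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT])
        assert c.category is SiteCategory.QUERY_RARE

    def test_het_counts_as_carrying_by_default(self):
        c = classify_one([HET, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HET])
        assert c.category is SiteCategory.DONOR_DIAGNOSTIC
        assert c.query_carries_donor_allele

    def test_hom_only_policy(self):
        c = classify_one(
            [HET, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HET],
            ClassificationPolicy(het_carries=False),
        )
        assert c.category is not SiteCategory.DONOR_DIAGNOSTIC
        assert not c.query_carries_donor_allele

    def test_missing_donor_blocks_diagnostic_at_zero_tolerance(self):
        c = classify_one([MISSING, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT])
        assert c.category is SiteCategory.QUERY_RARE
        assert c.n_missing == 1

    def test_missing_tolerance_allows_diagnostic(self):
        c = classify_one(
            [MISSING, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT],
            ClassificationPolicy(max_missing_fraction=0.5),
        )
        assert c.category is SiteCategory.DONOR_DIAGNOSTIC

    def test_bad_policy_rejected(self):
        with pytest.raises(ValueError):
            ClassificationPolicy(max_missing_fraction=1.5)

    def test_category_partition_property(self, rng):
        """Every random site gets exactly one category; counts add up."""
        n_sites, n_acc = 300, 6
        pos = np.sort(rng.choice(np.arange(1, 10**6), n_sites, replace=False))
        calls = rng.integers(-1, 3, size=(n_sites, n_acc))
        accs = ["d0", "d1", "w0", "w1", "w2", "q"]
        mat = matrix_from_columns(pos, calls.T, accs)
        out = classify_sites(mat, small_panel())
        assert len(out) == n_sites
        counts = {cat: 0 for cat in SiteCategory}
        for c in out:
            counts[c.category] += 1
        assert sum(counts.values()) == n_sites


class TestRestrictToRegion:
    def test_inclusive_bounds(self, rng):
        mat = matrix_from_columns([5, 15], [[0, 0]], ["a"])
        sub = restrict_to_region(mat, "chr6B", 1, 10)
        assert [s.pos for s in sub.sites] == [5]
        sub = restrict_to_region(mat, "chr6B", 5, 15)
        assert [s.pos for s in sub.sites] == [5, 15]

    def test_identity_and_brute_force(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 5000), 60, replace=False))
        calls = rng.integers(-1, 3, size=(60, 2))
        mat = matrix_from_columns(pos, calls.T, ["a", "b"])
        full = restrict_to_region(mat, "chr6B", 1, 5000)
        assert [s.pos for s in full.sites] == list(pos)
        for lo, hi in [(100, 900), (1, 1), (2500, 2500)]:
            sub = restrict_to_region(mat, "chr6B", lo, hi)
            expect = [int(p) for p in pos if lo <= p <= hi]
            assert [s.pos for s in sub.sites] == expect

    def test_unknown_chromosome(self):
        mat = matrix_from_columns([5], [[0]], ["a"])
        with pytest.raises(ValueError, match="unknown chromosome"):
            restrict_to_region(mat, "chr1A", 1, 10)

    def test_reversed_bounds(self):
        mat = matrix_from_columns([5], [[0]], ["a"])
        with pytest.raises(ValueError):
            restrict_to_region(mat, "chr6B", 10, 1)


def make_classified(positions, categories, query_flags, chrom="chr6B"):
    return [
        SiteClassification(
            site=VariantSite(chrom, int(p), "A", "G"),
            category=cat,
            query_carries_donor_allele=bool(q),
            n_missing=0,
        )
        for p, cat, q in zip(positions, categories, query_flags)
    ]


def brute_force_best_run(classified, params):
    """Exhaustive search over all contiguous support runs (test oracle)."""
    positions = np.array([c.site.pos for c in classified])
    supporting = np.array(
        [
            c.category is SiteCategory.DONOR_DIAGNOSTIC and c.query_carries_donor_allele
            for c in classified
        ]
    )
    sup = positions[supporting]
    best = None
    for i in range(len(sup)):
        for j in range(i, len(sup)):
            s, e = int(sup[i]), int(sup[j])
            run_sup = sup[(sup >= s) & (sup <= e)]
            if run_sup.size < params.min_support:
                continue
            if run_sup.size > 1 and np.diff(run_sup).max() > params.max_gap_bp:
                continue
            ok = True
            w = params.window_bp
            for m in range((s - 1) // w, (e - 1) // w + 1):
                a, b = m * w + 1, (m + 1) * w
                if a < s or b > e:
                    continue  # tile not fully inside the run
                in_w = (positions >= a) & (positions <= b)
                if in_w.sum() > 0 and supporting[in_w].sum() / in_w.sum() < params.min_window_fraction:
                    ok = False
                    break
            if not ok:
                continue
            key = (e - s, int(run_sup.size), s)
            if best is None or key > best:
                best = key
    return None if best is None else (best[2], best[2] + best[0])


class TestDetectSegment:
    def test_no_diagnostic_sites(self):
        cl = make_classified([10, 20], [SiteCategory.SHARED_WHEAT] * 2, [1, 1])
        assert detect_segment(cl) is None

    def test_breakpoint_worked_example(self):
        # dense diagnostic run ending at the known last alien SNP, then the
        # first wheat-type SNP beyond it
        sup_pos = list(range(35_000, 687_016_683, 500_000)) + [687_016_683]
        positions = sup_pos + [688_295_787]
        cats = [SiteCategory.DONOR_DIAGNOSTIC] * len(sup_pos) + [SiteCategory.SHARED_WHEAT]
        flags = [1] * len(positions)
        call = detect_segment(make_classified(positions, cats, flags))
        assert call is not None
        assert call.breakpoint_lo == 687_016_683
        assert call.breakpoint_hi == 688_295_787
        assert round(call.segment_end / 1e6, 2) == 687.02

    def test_chromosome_end_sentinel(self):
        pos = list(range(1000, 61_000, 1000))
        cats = [SiteCategory.DONOR_DIAGNOSTIC] * len(pos)
        call = detect_segment(
            make_classified(pos, cats, [1] * len(pos)),
            DetectionParams(min_support=5, window_bp=10_000, chrom_length=100_000),
        )
        assert call.breakpoint_hi == 100_001

    def test_unsorted_rejected(self):
        cl = make_classified([20, 10], [SiteCategory.DONOR_DIAGNOSTIC] * 2, [1, 1])
        with pytest.raises(ValueError, match="sorted"):
            detect_segment(cl)

    def test_monotonic_in_window_fraction(self, rng):
        """Raising min_window_fraction never lengthens the segment."""
        cl = self._random_classified(rng, 150)
        prev = None
        for frac in (0.2, 0.5, 0.8):
            params = DetectionParams(
                min_support=3, window_bp=1000, min_window_fraction=frac, max_gap_bp=3000
            )
            call = detect_segment(cl, params)
            span = -1 if call is None else call.segment_end - call.segment_start
            if prev is not None:
                assert span <= prev
            prev = span

    def _random_classified(self, rng, n):
        pos = np.sort(rng.choice(np.arange(1, 20_000), n, replace=False))
        pool = [SiteCategory.DONOR_DIAGNOSTIC, SiteCategory.SHARED_WHEAT, SiteCategory.UNINFORMATIVE]
        cats = [pool[i] for i in rng.choice(3, size=n, p=[0.8, 0.15, 0.05])]
        flags = rng.random(n) < 0.9
        return make_classified(pos, cats, flags)

    def test_matches_exhaustive_oracle(self, rng):
        """Implementation agrees with brute force on small random site lists."""
        params = DetectionParams(
            min_support=3, window_bp=1000, min_window_fraction=0.5, max_gap_bp=2500
        )
        n_checked = 0
        for _ in range(25):
            cl = self._random_classified(rng, int(rng.integers(20, 120)))
            expect = brute_force_best_run(cl, params)
            call = detect_segment(cl, params)
            if expect is None:
                assert call is None
            else:
                assert call is not None
                assert (call.segment_start, call.segment_end) == expect
                n_checked += 1
        assert n_checked >= 5  # the comparison must actually exercise calls
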