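import numpy as np
import pytest
from scipy import stats

from introscan.linkage import (
    GeneticMap,
    PlantRecord,
    build_genetic_map,
    chi2_segregation,
    classify_phenotype,
    count_recombinant_gametes,
    map_distance,
    read_population_tsv,
    resolve_gene_genotype,
    validate_marker_panel,
    write_population_tsv,
)
from introscan.synthetic import PopSimConfig, simulate_mapping_population


class TestInfectionTypes:
    @pytest.mark.parametrize(
        "raw,cls,binary",
        [
            ("0;", 0, "R"),
            (";", 0, "R"),
            (";1-", 1, "R"),
            ("1", 1, "R"),
            ("2+", 2, "R"),
            ("3+", 3, "S"),
            ("4", 4, "S"),
            ("3-4", 4, "S"),
            ("3–4", 4, "S"),  # en-dash range as printed in tables
        ],
    )
    def test_parsing(self, raw, cls, binary):
        it = classify_phenotype(raw)
        assert (it.numeric_class, it.binary) == (cls, binary)

    @pytest.mark.parametrize("raw", ["X?", "", "  ", "5", "R"])
    def test_unparseable_raises(self, raw):
        with pytest.raises(ValueError):
            classify_phenotype(raw)

    def test_threshold_configurable(self):
        assert classify_phenotype("2", threshold=1).binary == "S"
        assert classify_phenotype("3", threshold=3).binary == "R"


class TestChi2:
    def test_exact_fit_is_zero(self):
        assert chi2_segregation(75, 25).chi2 == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "n_R,n_S,expected",
        [(79, 38, 3.49), (132, 56, 2.30), (130, 57, 3.00)],
    )
    def test_printed_values(self, n_R, n_S, expected):
        assert round(chi2_segregation(n_R, n_S).chi2, 2) == expected

    def test_textbook_formula_cross_check(self, rng):
        """Matches scipy's Pearson chi-square for random integer counts."""
        for _ in range(50):
            n_R, n_S = int(rng.integers(1, 300)), int(rng.integers(1, 300))
            res = chi2_segregation(n_R, n_S, (3, 1))
            total = n_R + n_S
            ref = stats.chisquare([n_R, n_S], f_exp=[total * 0.75, total * 0.25])
            assert res.chi2 == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)

    def test_p_in_range(self):
        res = chi2_segregation(91, 45)
        assert 0 < res.p <= 1 and res.df == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            chi2_segregation(0, 0)
        with pytest.raises(ValueError):
            chi2_segregation(10, 5, (1, 0))


class TestGeneGenotype:
    def test_all_resistant(self):
        assert resolve_gene_genotype(["R"] * 25) == "RR"

    def test_segregating(self):
        assert resolve_gene_genotype(["R"] * 18 + ["S"] * 7) == "Rr"

    def test_all_susceptible(self):
        assert resolve_gene_genotype(["S"] * 20) == "rr"

    def test_small_family_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="min_family_size"):
            assert resolve_gene_genotype(["R"] * 5) == "UNKNOWN"

    def test_bad_phenotype(self):
        with pytest.raises(ValueError):
            resolve_gene_genotype(["R", "X"] * 10)


# minimal recombinant gametes for all 9 two-locus genotype combinations,
# enumerated by hand over the coupling-phase gamete pairs
HAND_TABLE = {
    ("A", "RR"): 0, ("A", "Rr"): 1, ("A", "rr"): 2,
    ("H", "RR"): 1, ("H", "Rr"): 0, ("H", "rr"): 1,
    ("B", "RR"): 2, ("B", "Rr"): 1, ("B", "rr"): 0,
}


class TestRecombinantCounting:
    @pytest.mark.parametrize("combo,expected", HAND_TABLE.items())
    def test_all_nine_combinations(self, combo, expected):
        assert count_recombinant_gametes(*combo) == expected

    def test_excluded_inputs(self):
        assert count_recombinant_gametes("MISSING", "Rr") is None
        assert count_recombinant_gametes("A", "UNKNOWN") is None

    def test_bad_codes(self):
        with pytest.raises(ValueError):
            count_recombinant_gametes("X", "Rr")
        with pytest.raises(ValueError):
            count_recombinant_gametes("A", "rR")


class TestMapDistance:
    @pytest.mark.parametrize(
        "rec,total,cm",
        [(18, 3892, 0.46), (11, 372, 2.96), (1, 376, 0.27), (0, 376, 0.0)],
    )
    def test_reported_distances(self, rec, total, cm):
        assert map_distance(rec, total) == cm

    def test_rounding_half_away_from_zero(self):
        assert map_distance(1, 800) == 0.13  # 0.125 rounds up, not to even

    def test_errors(self):
        with pytest.raises(ValueError):
            map_distance(1, 0)
        with pytest.raises(ValueError):
            map_distance(5, 4)


def plants_from_doses(dose_rows, loci, gene):
    code = {2: "A", 1: "H", 0: "B"}
    geno = {2: "RR", 1: "Rr", 0: "rr"}
    out = []
    for i, row in enumerate(dose_rows):
        markers = {l: code[d] for l, d in zip(loci, row) if l != gene}
        g = geno[row[loci.index(gene)]]
        out.append(PlantRecord(id=f"p{i}", marker_genotypes=markers, gene_genotype=g))
    return out


class TestGeneticMap:
    def test_complete_linkage_single_group(self):
        plants = plants_from_doses([(1, 1)] * 40 + [(2, 2)] * 10, ["m1", "g"], "g")
        gmap = build_genetic_map(plants, ["m1", "g"], gene="g")
        assert gmap.positions_cM == [0.0, 0.0]
        assert gmap.cosegregation_groups == [["m1", "g"]]

    def test_single_recombinant_in_376_gametes(self):
        rows = [(1, 1)] * 187 + [(2, 1)]  # one (A, Rr) plant: 1 recombinant gamete
        plants = plants_from_doses(rows, ["g", "m1"], "g")
        gmap = build_genetic_map(plants, ["g", "m1"], gene="g")
        assert gmap.interval_recombinants == [1]
        assert gmap.interval_totals == [376]
        assert gmap.positions_cM == [0.0, 0.27]

    def test_simulated_truth_recovered_exactly(self):
        cfg = PopSimConfig(
            seed=11,
            n_plants=200,
            loci=("m1", "g", "m2"),
            gene="g",
            r=(0.0, 0.0),
            forced_recombinants=((0, 3), (1, 5)),
        )
        plants, truth = simulate_mapping_population(cfg)
        gmap = build_genetic_map(plants, list(cfg.loci), gene="g")
        assert gmap.interval_recombinants == truth.interval_recombinants.tolist() == [3, 5]
        assert gmap.interval_totals == [400, 400]

    def test_plant_order_invariance(self, rng):
        cfg = PopSimConfig(seed=5, n_plants=150, r=(0.01, 0.02))
        plants, _ = simulate_mapping_population(cfg)
        gmap1 = build_genetic_map(plants, list(cfg.loci), gene=cfg.gene)
        shuffled = list(plants)
        rng.shuffle(shuffled)
        gmap2 = build_genetic_map(shuffled, list(cfg.loci), gene=cfg.gene)
        assert gmap1.positions_cM == gmap2.positions_cM
        assert gmap1.interval_recombinants == gmap2.interval_recombinants

    def test_anchor_order_enforced(self):
        plants = plants_from_doses([(1, 1)] * 20, ["m1", "g"], "g")
        with pytest.raises(ValueError, match="anchor order"):
            build_genetic_map(plants, ["m1", "g"], gene="g", anchor={"m1": 5.0, "g": 1.0})

    def test_unscored_locus_rejected(self):
        plants = plants_from_doses([(1, 1)] * 20, ["m1", "g"], "g")
        with pytest.raises(ValueError, match="unscored"):
            build_genetic_map(plants, ["m1", "g", "m9"], gene="g")

    def test_recombination_fraction_recovery(self):
        """Estimated cM within 2 binomial SE of truth at several r."""
        for r, seed in [(0.005, 101), (0.01, 202), (0.05, 303)]:
            ests = []
            for rep in range(30):
                cfg = PopSimConfig(
                    seed=seed + rep, n_plants=1000, loci=("m", "g"), gene="g", r=(r,)
                )
                plants, _ = simulate_mapping_population(cfg)
                gmap = build_genetic_map(plants, ["m", "g"], gene="g")
                ests.append(gmap.interval_recombinants[0] / gmap.interval_totals[0])
            se = np.sqrt(r * (1 - r) / 2000)
            assert abs(np.mean(ests) - r) <= 2 * se


class TestMarkerPanel:
    def _calls(self, n_amp, n_total, group, marker="pku6B3127"):
        calls = {}
        groups = {}
        for i in range(n_total):
            acc = f"{group}_{i}"
            calls[acc] = {marker: "418+700" if i < n_amp else None}
            groups[acc] = group
        return calls, groups

    def test_reported_percentages(self):
        calls_t, groups_t = self._calls(73, 87, "turgidum")
        calls_a, groups_a = self._calls(53, 149, "aestivum")
        summary = validate_marker_panel(
            {**calls_t, **calls_a},
            {"pku6B3127": "418+700"},
            groups={**groups_t, **groups_a},
        )
        assert summary.per_marker["pku6B3127"]["turgidum"] == (73, 87, 83.9)
        assert summary.per_marker["pku6B3127"]["aestivum"] == (53, 149, 35.6)

    def test_haplotype_identity_requires_all_markers(self):
        ref = {"m1": "a", "m2": "b"}
        calls = {
            "x": {"m1": "a", "m2": "b"},
            "y": {"m1": "a", "m2": "c"},
            "z": {"m1": "a", "m2": None},
        }
        summary = validate_marker_panel(calls, ref)
        assert summary.n_haplotype_identical == 1
        assert summary.identical_accessions == ["x"]

    def test_all_missing(self):
        calls = {f"a{i}": {"m": None} for i in range(5)}
        summary = validate_marker_panel(calls, {"m": "x"})
        assert summary.per_marker["m"]["all"] == (0, 5, 0.0)
        assert summary.n_haplotype_identical == 0


class TestPopulationTsv:
    def test_round_trip(self, tmp_path):
        cfg = PopSimConfig(seed=3, n_plants=25, r=(0.0, 0.05))
        plants, _ = simulate_mapping_population(cfg)
        write_population_tsv(plants, tmp_path / "pop.tsv")
        back = read_population_tsv(tmp_path / "pop.tsv")
        assert len(back) == 25
        for a, b in zip(plants, back):
            assert a.id == b.id
            assert a.marker_genotypes == b.marker_genotypes
            assert a.gene_genotype == b.gene_genotype
            assert a.phenotype.raw == b.phenotype.raw

    def test_bad_gene_genotype_rejected(self, tmp_path):
        (tmp_path / "pop.tsv").write_text("id\tm1\tinfection_type\tgene_genotype\np1\tA\t0;\tXY\n")
        with pytest.raises(ValueError, match="gene_genotype"):
            read_population_tsv(tmp_path / "pop.tsv")
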