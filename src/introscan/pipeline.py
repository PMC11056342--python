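"""End-to-end orchestration of the origin and mapping analyses.

A run is driven by a :class:`RunConfig` (usually loaded from YAML). Every
run writes a resolved copy of its configuration and a plain-text log naming
every parameter actually used next to its outputs, so a finished results
directory is self-describing.

Exit-code contract for scripts wrapping these functions: 0 success, 2 input
error, 3 no-call (no qualifying segment found).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import linkage, panel_io, phylogeny, scan, synthetic

log = logging.getLogger(__name__)

EXIT_OK, EXIT_INPUT_ERROR, EXIT_NO_CALL = 0, 2, 3


def _build(cls, d: dict):
    """Instantiate a (nested) dataclass from a dict, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(d).__name__}")
    names = {f.name: f for f in fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        t = names[k].type
        sub = _NESTED.get((cls.__name__, k))
        kwargs[k] = _build(sub, v) if sub is not None and isinstance(v, dict) else v
    return cls(**kwargs)


@dataclass
class OriginStageConfig:
    vcf: str | None = None  # genotype input; None -> simulate
    panel: str | None = None  # panel metadata TSV; None -> simulated panel
    chrom: str | None = None
    policy: dict = field(default_factory=dict)  # ClassificationPolicy kwargs
    detection: dict = field(default_factory=dict)  # DetectionParams kwargs
    nj_min_overlap: int = 50
    nj_het_weight: float = 0.5
    simulate: dict = field(default_factory=dict)  # PanelSimConfig overrides


@dataclass
class MappingStageConfig:
    population: str | None = None  # population TSV; None -> simulate
    loci: list[str] | None = None
    gene: str | None = None
    ratio: tuple[float, float] = (3, 1)
    resistance_threshold: int = 2
    simulate: dict = field(default_factory=dict)  # PopSimConfig overrides


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results/run"
    stages: list[str] = field(default_factory=lambda: ["origin", "mapping"])
    origin: OriginStageConfig = field(default_factory=OriginStageConfig)
    mapping: MappingStageConfig = field(default_factory=MappingStageConfig)


_NESTED = {
    ("RunConfig", "origin"): OriginStageConfig,
    ("RunConfig", "mapping"): MappingStageConfig,
}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _build(RunConfig, raw)


def _resolved_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


class _RunLogger:
    """File log that records every parameter the run actually used."""

    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def param(self, name: str, value) -> None:
        self.lines.append(f"param {name}={value!r}")

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _log_params(rl: _RunLogger, prefix: str, obj) -> None:
    for f in fields(obj):
        rl.param(f"{prefix}.{f.name}", getattr(obj, f.name))


def run_origin_analysis(cfg: RunConfig) -> dict:
    """Classify, locate the segment, and place the query on the NJ tree.

    Writes classification TSV, segment BED, density TSV, distance TSV,
    Newick tree, summary JSON, a resolved-config copy and the parameter
    log under ``cfg.out_dir``. Returns the summary dict (``status`` is
    "ok" or "no_call").
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rl = _RunLogger(out / "origin.log")
    rl.param("seed", cfg.seed)

    o = cfg.origin
    if o.vcf is not None:
        mat = panel_io.read_genotype_table(o.vcf, format="vcf")
        if o.panel is None:
            raise ValueError("a panel metadata TSV is required with --vcf input")
        panel = panel_io.read_panel_metadata(o.panel)
        rl.param("origin.vcf", o.vcf)
        rl.param("origin.panel", o.panel)
    else:
        sim_cfg = synthetic.PanelSimConfig(seed=cfg.seed, **o.simulate)
        _log_params(rl, "origin.simulate", sim_cfg)
        mat, truth = synthetic.simulate_species_panel(sim_cfg)
        panel = truth.panel

    policy = scan.ClassificationPolicy(**o.policy)
    _log_params(rl, "origin.policy", policy)
    params = scan.DetectionParams(**o.detection)
    _log_params(rl, "origin.detection", params)
    rl.param("origin.nj_min_overlap", o.nj_min_overlap)
    rl.param("origin.nj_het_weight", o.nj_het_weight)

    chrom = o.chrom or mat.chroms()[0]
    rl.param("origin.chrom", chrom)
    region = scan.restrict_to_region(mat, chrom, 1, 2**62)
    classified = scan.classify_sites(region, panel, policy)
    scan.write_classification_tsv(classified, out / "classification.tsv")

    counts = {c.value: 0 for c in scan.SiteCategory}
    for c in classified:
        counts[c.category.value] += 1

    call = scan.detect_segment(classified, params)
    summary: dict = {
        "n_sites": len(classified),
        "category_counts": counts,
        "chrom": chrom,
    }
    if call is None:
        summary["status"] = "no_call"
        panel_io.write_segment_bed(None, out / "segment.bed")
        rl.info("no qualifying segment found")
    else:
        summary["status"] = "ok"
        summary["segment"] = {
            "start": call.segment_start,
            "end": call.segment_end,
            "breakpoint_lo": call.breakpoint_lo,
            "breakpoint_hi": call.breakpoint_hi,
            "n_support": call.n_support,
            "length_Mb": round(call.segment_end / 1e6, 2),
        }
        panel_io.write_segment_bed(call, out / "segment.bed")
        scan.write_density_tsv(call, out / "density.tsv")

        seg_mat = scan.restrict_to_region(mat, chrom, call.segment_start, call.segment_end)
        try:
            D = phylogeny.p_distance_matrix(
                seg_mat, min_overlap=o.nj_min_overlap, het_weight=o.nj_het_weight
            )
            tree = phylogeny.neighbor_joining(D)
            phylogeny.write_newick(tree, out / "tree.nwk")
            phylogeny.write_distance_tsv(D, out / "distances.tsv")
            query = next(a.id for a in panel if a.group is panel_io.Group.QUERY)
            donors = {a.id for a in panel if a.group is panel_io.Group.DONOR_CANDIDATE}
            summary["query_in_donor_clade"] = phylogeny.query_neighbor_clade(
                tree, query, donors
            )
        except ValueError as exc:
            raise RuntimeError(f"stage phylogeny failed: {exc}") from exc

    (out / "origin_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "origin_config.yaml").write_text(yaml.safe_dump(_resolved_dict(cfg)))
    rl.flush()
    return summary


def run_mapping_analysis(cfg: RunConfig) -> dict:
    """Segregation test and genetic-map construction; returns the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rl = _RunLogger(out / "mapping.log")
    rl.param("seed", cfg.seed)

    m = cfg.mapping
    rl.param("mapping.ratio", m.ratio)
    rl.param("mapping.resistance_threshold", m.resistance_threshold)
    if m.population is not None:
        marker_loci = None if m.loci is None else [l for l in m.loci if l != m.gene]
        population = linkage.read_population_tsv(m.population, loci=marker_loci)
        loci = m.loci or sorted({k for p in population for k in p.marker_genotypes})
        gene = m.gene
        rl.param("mapping.population", m.population)
    else:
        sim_cfg = synthetic.PopSimConfig(seed=cfg.seed, **m.simulate)
        _log_params(rl, "mapping.simulate", sim_cfg)
        population, _truth = synthetic.simulate_mapping_population(sim_cfg)
        loci = list(m.loci or sim_cfg.loci)
        gene = m.gene or sim_cfg.gene
    rl.param("mapping.loci", loci)
    rl.param("mapping.gene", gene)

    n_R = sum(1 for p in population if p.phenotype and p.phenotype.binary == "R")
    n_S = sum(1 for p in population if p.phenotype and p.phenotype.binary == "S")
    report: dict = {"n_R": n_R, "n_S": n_S}
    try:
        seg = linkage.chi2_segregation(n_R, n_S, tuple(m.ratio))
        report["segregation"] = {
            "ratio": list(m.ratio),
            "chi2": round(seg.chi2, 2),
            "p": round(seg.p, 4),
        }
    except ValueError as exc:
        # e.g. an all-resistant population: report the failure, don't crash
        report["segregation"] = {"ratio": list(m.ratio), "error": str(exc)}
        rl.info(f"segregation test not applicable: {exc}")

    gmap = linkage.build_genetic_map(population, loci, gene=gene)
    report["map"] = {
        "loci": gmap.loci,
        "positions_cM": gmap.positions_cM,
        "interval_recombinants": gmap.interval_recombinants,
        "interval_totals": gmap.interval_totals,
        "cosegregation_groups": gmap.cosegregation_groups,
    }
    n_flagged = sum(1 for p in population if p.is_inconsistent())
    report["n_phenotype_genotype_inconsistent"] = n_flagged

    linkage.write_map_text(gmap, out / "genetic_map.txt")
    (out / "mapping_report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "mapping_config.yaml").write_text(yaml.safe_dump(_resolved_dict(cfg)))
    rl.flush()
    return report
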