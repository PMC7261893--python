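"""End-to-end orchestration: QC -> phasing -> crossovers / distortion scan /
diversity, with a manifest and a human-readable report.

Every table the run writes is reproducible from the manifest: it records
input checksums, all parameters, and the package version.  Stage failures
abort with a stage-labeled error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crossover_analysis import (
    CrossoverSummary,
    count_per_arm,
    detect_switches,
    interval_recombination,
    max_crossovers,
)
from .diversity import TreeReport, nj_tree, population_tree_report, simple_matching
from .marker_io import (
    GenotypeMatrix,
    MarkerMap,
    QCReport,
    qc_filter,
    read_centromeres,
    read_genotypes,
    read_marker_map,
    write_table,
)
from .origin_phasing import OriginMatrix, assign_origin, phase_from_map, read_phase
from .seg_distortion import (
    PopulationComparison,
    SDScanResult,
    allele_counts,
    compare_populations,
    male_haplotype_matrix,
    sd_regions,
    sd_scan,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    genotypes: str
    marker_map: str
    out_dir: str
    centromeres: str | None = None
    phase: str | None = None
    progeny_genotypes: str | None = None
    alpha: float = 0.05
    qc_threshold: float = 0.65
    chromosomes: list[int] | None = None
    min_run: int = 2
    seed: int = 0
    log_level: str = "INFO"
    dialect: str = "tsv"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ReportBundle:
    qc: QCReport
    origins: OriginMatrix
    crossovers: dict[int, CrossoverSummary]
    intervals: dict[int, pd.DataFrame]
    pollen_scan: SDScanResult
    progeny_scan: SDScanResult | None = None
    comparison: PopulationComparison | None = None
    regions: dict[str, list] = field(default_factory=dict)
    tree_report: TreeReport | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@_stage("load")
def _load(cfg: RunConfig):
    mmap = read_marker_map(cfg.marker_map, dialect=cfg.dialect)
    if cfg.centromeres:
        mmap.centromere_cm = read_centromeres(cfg.centromeres, dialect=cfg.dialect)
    gm = read_genotypes(cfg.genotypes, mmap, ploidy=1, dialect=cfg.dialect)
    progeny = None
    if cfg.progeny_genotypes:
        progeny = read_genotypes(
            cfg.progeny_genotypes, mmap, ploidy=2, dialect=cfg.dialect
        )
    return mmap, gm, progeny


def run_all(cfg: RunConfig) -> ReportBundle:
    """Run the full analysis and write all tables under cfg.out_dir."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mmap, gm, progeny = _load(cfg)

    qc = _stage("qc")(qc_filter)(gm, cfg.qc_threshold)
    retained = gm.subset(qc.retained_units)
    write_table(qc, out / "qc.tsv", dialect=cfg.dialect)

    if cfg.phase:
        phase = _stage("phase")(read_phase)(cfg.phase, dialect=cfg.dialect)
    else:
        phase = phase_from_map(mmap)
    origins = _stage("phase")(assign_origin)(retained, mmap, phase)
    write_table(origins, out / "origins.tsv", dialect=cfg.dialect)

    chroms = cfg.chromosomes
    if chroms is None:
        chroms = [
            lg
            for lg in mmap.linkage_groups
            if len(mmap.chromosome(lg)) >= 2 and lg in mmap.centromere_cm
        ]
    crossovers: dict[int, CrossoverSummary] = {}
    intervals: dict[int, pd.DataFrame] = {}
    for lg in chroms:
        sw = _stage("crossovers")(detect_switches)(origins, mmap, lg)
        summary = _stage("crossovers")(count_per_arm)(sw, mmap)
        crossovers[lg] = summary
        intervals[lg] = _stage("crossovers")(interval_recombination)(
            origins, mmap, lg
        )
        write_table(summary, out / f"crossovers_chr{lg}.tsv", dialect=cfg.dialect)
        write_table(
            intervals[lg], out / f"intervals_chr{lg}.tsv", dialect=cfg.dialect
        )

    counts = _stage("sdscan")(allele_counts)(retained, mmap)
    pollen_scan = _stage("sdscan")(sd_scan)(
        counts, alpha=cfg.alpha, population_label="pollen"
    )
    write_table(pollen_scan, out / "sd_pollen.tsv", dialect=cfg.dialect)
    regions = {"pollen": sd_regions(pollen_scan, mmap, cfg.min_run)}

    progeny_scan = comparison = tree_report = None
    if progeny is not None:
        pcounts = _stage("sdscan")(allele_counts)(progeny, mmap)
        progeny_scan = _stage("sdscan")(sd_scan)(
            pcounts, alpha=cfg.alpha, population_label="progeny"
        )
        write_table(progeny_scan, out / "sd_progeny.tsv", dialect=cfg.dialect)
        comparison = _stage("sdcompare")(compare_populations)(
            pollen_scan, progeny_scan
        )
        write_table(comparison, out / "sd_comparison.tsv", dialect=cfg.dialect)
        regions["progeny"] = sd_regions(progeny_scan, mmap, cfg.min_run)
        haplos = _stage("diversity")(male_haplotype_matrix)(progeny, mmap)
        tree_report = _stage("diversity")(population_tree_report)(
            retained, haplos, label_a="pollen", label_b="progeny_male"
        )
        (out / "tree.nwk").write_text(tree_report.tree.newick() + "\n")
        write_table(tree_report.labels_frame(), out / "tree_labels.tsv")
    elif retained.n_units >= 3:
        tree = _stage("diversity")(nj_tree)(simple_matching(retained))
        (out / "tree.nwk").write_text(tree.newick() + "\n")

    bundle = ReportBundle(
        qc=qc,
        origins=origins,
        crossovers=crossovers,
        intervals=intervals,
        pollen_scan=pollen_scan,
        progeny_scan=progeny_scan,
        comparison=comparison,
        regions=regions,
        tree_report=tree_report,
    )
    (out / "report.md").write_text(make_paper_style_report(bundle))
    _write_manifest(cfg, out)
    return bundle


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    inputs = {}
    for name in ("genotypes", "marker_map", "centromeres", "phase", "progeny_genotypes"):
        path = getattr(cfg, name)
        if path:
            inputs[name] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {
        "pollenscan_version": __version__,
        "inputs": inputs,
        "parameters": {
            "alpha": cfg.alpha,
            "qc_threshold": cfg.qc_threshold,
            "chromosomes": cfg.chromosomes,
            "min_run": cfg.min_run,
            "seed": cfg.seed,
            "dialect": cfg.dialect,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _scan_section(scan: SDScanResult | None, title: str) -> list[str]:
    lines = [f"## Segregation distortion - {title}", ""]
    if scan is None or len(scan.table) == 0:
        lines += ["no markers tested", ""]
        return lines
    tbl = scan.table.reset_index()[
        ["locus", "lg", "cm", "a1", "a2", "chi_square", "p_value", "distorted"]
    ].copy()
    tbl["chi_square"] = tbl["chi_square"].map(lambda v: f"{v:.3f}")
    tbl["p_value"] = tbl["p_value"].map(lambda v: f"{v:.3f}")
    lines += [
        tbl.to_string(index=False),
        "",
        f"distorted: {scan.n_distorted}/{scan.n_tested} "
        f"({100 * scan.distortion_rate:.1f}%) at alpha = {scan.alpha}",
        "",
    ]
    return lines


def make_paper_style_report(bundle: ReportBundle) -> str:
    """Render the analysis as markdown: QC accounting, the per-chromosome
    crossover cross-tab (arm 1 counts as columns, arm 2 as rows), interval
    recombination ratios, and the distortion scans per population."""
    lines = ["# pollenscan report", ""]
    qc = bundle.qc
    lines += [
        "## Gamete QC",
        "",
        f"retained {qc.n_retained}/{len(qc.per_unit_positive_rate)} gametes "
        f"({100 * qc.retention_rate:.1f}%) at threshold {qc.threshold:.2f}; "
        f"positive calls among retained: {100 * qc.overall_positive_rate:.1f}%",
        "",
    ]
    for lg, summary in bundle.crossovers.items():
        lines += [f"## Crossovers - chromosome {lg}", ""]
        if summary.n_gametes_analyzed == 0:
            lines += ["no gametes analyzable", ""]
            continue
        lines += [
            summary.distribution_table().to_string(),
            "",
            f"gametes analyzed: {summary.n_gametes_analyzed}; "
            f"mean crossovers/chromosome: {summary.mean_co_per_chromosome:.2f}; "
            f"no-crossover gametes: {100 * summary.zero_co_fraction:.1f}%; "
            f"per-arm maxima: {max_crossovers(summary)}",
            "",
        ]
    lines += _scan_section(bundle.pollen_scan, "pollen population")
    if bundle.progeny_scan is not None:
        lines += _scan_section(bundle.progeny_scan, "progeny population")
    if bundle.comparison is not None:
        c = bundle.comparison
        lines += [
            "## Population contrast",
            "",
            f"distorted in both: {c.n_both}; {c.label_a} only: {c.n_a_only}; "
            f"{c.label_b} only: {c.n_b_only}; union: {c.n_union}",
            "",
        ]
    for pop, regs in bundle.regions.items():
        if regs:
            lines += [f"## Distortion regions - {pop}", ""]
            for r in regs:
                lines.append(
                    f"- LG {r.linkage_group}: {', '.join(r.member_loci)} "
                    f"({r.span_cm[0]:.2f}-{r.span_cm[1]:.2f} cM)"
                )
            lines.append("")
    if bundle.tree_report is not None:
        n_excl = bundle.tree_report.exclusivity_count()
        lines += [
            "## Diversity",
            "",
            f"single-population clades (>= {bundle.tree_report.min_clade_size} "
            f"leaves): {n_excl}",
            "",
        ]
    return "\n".join(lines)
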