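"""Chi-square scanning for allelic transmission-ratio distortion.

Every marker heterozygous in the focal (male) parent is tested against the
Mendelian 1:1 gametic expectation with an uncorrected one-degree-of-freedom
chi-square, chi2 = (a1 - a2)^2 / (a1 + a2).  Counts come either from a
haploid gamete matrix directly, or from diploid progeny by decomposing each
genotype into a focal-parent and an other-parent allele; decompositions in
which both parents could have supplied both observed alleles are ambiguous
and are excluded (with an audit count) rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .marker_io import GenotypeMatrix, MarkerDef, MarkerMap

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["a1", "a2", "n_ambiguous", "n_off_ladder", "n_missing"]


def chi_square_1to1(a1: int, a2: int) -> tuple[float, float]:
    """Chi-square statistic and upper-tail p-value (1 df) for a 1:1 test.

    No continuity correction is applied.
    """
    n = a1 + a2
    if n <= 0:
        raise ValueError("chi_square_1to1 needs a1 + a2 > 0")
    chi = (a1 - a2) ** 2 / n
    return float(chi), float(stats.chi2.sf(chi, df=1))


def _decompose_diploid(
    call: str, focal: tuple[str, str], other: tuple[str, str]
) -> str | None:
    """Focal-parent allele transmitted in a diploid call, brute-forcing the
    2x2 parental decompositions.

    Returns the unique focal allele, "AMBIGUOUS" when both decompositions
    are valid, or None when no decomposition exists (off-ladder call).
    """
    obs = sorted(call.split("/"))
    candidates = {
        f
        for f in set(focal)
        for o in set(other)
        if sorted([f, o]) == obs
    }
    if not candidates:
        return None
    if len(candidates) > 1:
        return "AMBIGUOUS"
    return candidates.pop()


def _focal_pair(marker: MarkerDef, parent: int) -> tuple[str, str]:
    return marker.parent1_alleles if parent == 1 else marker.parent2_alleles


def _other_pair(marker: MarkerDef, parent: int) -> tuple[str, str]:
    return marker.parent2_alleles if parent == 1 else marker.parent1_alleles


def allele_counts(
    gm: GenotypeMatrix, mmap: MarkerMap, parent: int = 1
) -> pd.DataFrame:
    """Per-marker counts of the focal parent's allele 1 vs allele 2.

    Haploid units count their single call; diploid units are decomposed
    against the other parent's alleles.  The result is indexed by locus and
    carries audit columns for ambiguous, off-ladder and missing units plus
    a ``usable`` flag (a marker with no countable unit, e.g. one where the
    focal alleles are indistinguishable, is unusable).
    """
    rows = {}
    for m in mmap.markers:
        if m.locus_id not in set(gm.loci):
            continue
        focal = _focal_pair(m, parent)
        other = _other_pair(m, parent)
        a1 = a2 = amb = off = miss = 0
        for call in gm.calls[m.locus_id]:
            if pd.isna(call):
                miss += 1
                continue
            call = str(call)
            if gm.ploidy == 1:
                allele = call if call in set(focal) else None
            else:
                allele = _decompose_diploid(call, focal, other)
            if allele is None:
                off += 1
            elif allele == "AMBIGUOUS" or focal[0] == focal[1]:
                amb += 1
            elif allele == focal[0]:
                a1 += 1
            else:
                a2 += 1
        if amb:
            logger.info("%s: %d ambiguous unit(s) excluded", m.locus_id, amb)
        rows[m.locus_id] = {
            "lg": m.linkage_group,
            "cm": m.position_cm,
            "a1": a1,
            "a2": a2,
            "n_ambiguous": amb,
            "n_off_ladder": off,
            "n_missing": miss,
            "usable": (a1 + a2) > 0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "locus"
    return out


def male_haplotype_matrix(
    gm: GenotypeMatrix, mmap: MarkerMap, parent: int = 1
) -> GenotypeMatrix:
    """Extract the focal-parent-transmitted haploid genotype from diploid
    progeny (ambiguous or off-ladder decompositions become missing)."""
    if gm.ploidy != 2:
        raise ValueError("male_haplotype_matrix expects a diploid matrix")
    cols = {}
    for m in mmap.markers:
        if m.locus_id not in set(gm.loci):
            continue
        focal = _focal_pair(m, parent)
        other = _other_pair(m, parent)

        def pull(call):
            if pd.isna(call):
                return np.nan
            allele = _decompose_diploid(str(call), focal, other)
            if allele is None or allele == "AMBIGUOUS":
                return np.nan
            return allele

        cols[m.locus_id] = gm.calls[m.locus_id].map(pull)
    return GenotypeMatrix(
        calls=pd.DataFrame(cols, index=gm.calls.index), ploidy=1
    )


@dataclass
class SDScanResult:
    """Chi-square scan over a marker panel for one population."""

    table: pd.DataFrame  # locus-indexed: lg cm a1 a2 chi_square p_value distorted
    alpha: float
    population_label: str = ""

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    @property
    def n_distorted(self) -> int:
        return int(self.table["distorted"].sum())

    @property
    def distortion_rate(self) -> float:
        return self.n_distorted / self.n_tested

    def distorted_loci(self) -> list[str]:
        return list(self.table.index[self.table["distorted"]])

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def sd_scan(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    population_label: str = "",
    correction: str | None = None,
) -> SDScanResult:
    """Test every usable marker for 1:1 distortion.

    ``counts`` is an allele_counts-style frame (locus-indexed with a1/a2
    and optionally lg/cm).  Per-marker tests are not multiplicity-corrected
    by default; ``correction`` may be "bonferroni" or "bh" to adjust the
    p-values used for the distorted flag.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in (None, "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    table = counts.copy()
    for col in ("lg", "cm"):
        if col not in table.columns:
            table[col] = np.nan
    totals = table["a1"] + table["a2"]
    tested = totals > 0
    chi = np.full(len(table), np.nan)
    pval = np.full(len(table), np.nan)
    for k, (a1, a2) in enumerate(zip(table["a1"], table["a2"])):
        if a1 + a2 > 0:
            chi[k], pval[k] = chi_square_1to1(int(a1), int(a2))
    table["chi_square"] = chi
    table["p_value"] = pval
    adj = pval.copy()
    idx = np.flatnonzero(tested.to_numpy())
    if correction == "bonferroni":
        adj[idx] = np.minimum(pval[idx] * idx.size, 1.0)
    elif correction == "bh":
        adj[idx] = stats.false_discovery_control(pval[idx], method="bh")
    table["tested"] = tested
    table["distorted"] = tested & (adj < alpha)
    return SDScanResult(table=table, alpha=alpha, population_label=population_label)


@dataclass(frozen=True)
class SDRegion:
    """A run of consecutive distorted markers on one linkage group."""

    linkage_group: int
    member_loci: tuple[str, ...]
    span_cm: tuple[float, float]


def sd_regions(
    scan: SDScanResult, mmap: MarkerMap, min_run: int = 2
) -> list[SDRegion]:
    """Maximal runs of consecutive distorted markers per linkage group with
    length >= min_run (distortion tends to cluster around a selected locus
    through hitchhiking of linked markers)."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    distorted = set(scan.distorted_loci())
    regions: list[SDRegion] = []
    for lg in mmap.linkage_groups:
        run: list[MarkerDef] = []
        chrom = [
            m for m in mmap.chromosome(lg) if m.locus_id in set(scan.table.index)
        ]
        for m in chrom + [None]:
            if m is not None and m.locus_id in distorted:
                run.append(m)
                continue
            if len(run) >= min_run:
                regions.append(
                    SDRegion(
                        linkage_group=lg,
                        member_loci=tuple(r.locus_id for r in run),
                        span_cm=(run[0].position_cm, run[-1].position_cm),
                    )
                )
            run = []
    return regions


@dataclass
class PopulationComparison:
    """Marker-by-marker concordance of two distortion scans."""

    table: pd.DataFrame  # locus-indexed with column "status"
    label_a: str
    label_b: str

    @property
    def n_both(self) -> int:
        return int((self.table["status"] == "both").sum())

    @property
    def n_a_only(self) -> int:
        return int((self.table["status"] == "a_only").sum())

    @property
    def n_b_only(self) -> int:
        return int((self.table["status"] == "b_only").sum())

    @property
    def n_union(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()


def compare_populations(
    scan_a: SDScanResult, scan_b: SDScanResult
) -> PopulationComparison:
    """Classify each marker as distorted in both scans, one, or neither."""
    if list(scan_a.table.index) != list(scan_b.table.index):
        raise ValueError("population scans cover different marker panels")
    in_a = scan_a.table["distorted"]
    in_b = scan_b.table["distorted"]
    status = np.select(
        [in_a & in_b, in_a & ~in_b, ~in_a & in_b],
        ["both", "a_only", "b_only"],
        default="neither",
    )
    table = pd.DataFrame(
        {
            "lg": scan_a.table["lg"],
            "cm": scan_a.table["cm"],
            "status": status,
        },
        index=scan_a.table.index,
    )
    return PopulationComparison(
        table=table,
        label_a=scan_a.population_label or "a",
        label_b=scan_b.population_label or "b",
    )
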