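"""Crossover detection, per-arm counting, and interval recombination.

A crossover is observed as a switch of parental origin between two
*consecutive informative* markers of a gamete (P1/P2 calls only).  Marker
pairs with an uninformative flank are skipped: the switch, if any, is
recorded on the merged interval spanning the skipped loci, and one switch
counts as exactly one crossover regardless of interval length (an even
number of true crossovers inside an interval is invisible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_io import MarkerMap
from .origin_phasing import INFORMATIVE, OriginMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Switch:
    """One detected origin switch between consecutive informative markers
    (indices are positions within the chromosome's ordered marker list)."""

    left: int
    right: int
    left_locus: str
    right_locus: str
    left_cm: float
    right_cm: float


@dataclass
class ChromosomeSwitches:
    chromosome: int
    loci: list[str]
    positions_cm: list[float]
    switches: dict[str, list[Switch]]
    informative_idx: dict[str, list[int]]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def analyzed_units(self) -> list[str]:
        return list(self.switches)

    def total_switches(self) -> int:
        return sum(len(v) for v in self.switches.values())


@dataclass
class CrossoverSummary:
    """Per-gamete per-arm crossover counts for one chromosome, with the
    population cross-tabulation and summary statistics."""

    per_gamete_arm_counts: dict[str, tuple[int, int]]
    chromosome: int | None = None

    @property
    def n_gametes_analyzed(self) -> int:
        return len(self.per_gamete_arm_counts)

    @property
    def distribution(self) -> dict[tuple[int, int], int]:
        dist: dict[tuple[int, int], int] = {}
        for counts in self.per_gamete_arm_counts.values():
            dist[counts] = dist.get(counts, 0) + 1
        return dist

    @property
    def mean_co_per_chromosome(self) -> float:
        n = self.n_gametes_analyzed
        if n == 0:
            raise ValueError("empty crossover summary")
        total = sum(a + b for a, b in self.per_gamete_arm_counts.values())
        return total / n

    @property
    def zero_co_fraction(self) -> float:
        n = self.n_gametes_analyzed
        if n == 0:
            raise ValueError("empty crossover summary")
        zeros = sum(
            1 for a, b in self.per_gamete_arm_counts.values() if a + b == 0
        )
        return zeros / n

    @classmethod
    def from_distribution(
        cls, distribution: dict[tuple[int, int], int], chromosome: int | None = None
    ) -> "CrossoverSummary":
        """Reconstruct a summary from an (arm1, arm2) -> n_gametes
        cross-tabulation (synthetic gamete ids are generated)."""
        counts: dict[str, tuple[int, int]] = {}
        i = 0
        for (a1, a2), n in sorted(distribution.items()):
            for _ in range(int(n)):
                i += 1
                counts[f"unit{i:04d}"] = (int(a1), int(a2))
        return cls(per_gamete_arm_counts=counts, chromosome=chromosome)

    def distribution_table(self) -> pd.DataFrame:
        """Cross-tab with arm-1 counts as columns and arm-2 counts as rows."""
        dist = self.distribution
        max1 = max((a for a, _ in dist), default=0)
        max2 = max((b for _, b in dist), default=0)
        table = pd.DataFrame(
            0,
            index=pd.Index(range(max2 + 1), name="arm2"),
            columns=pd.Index(range(max1 + 1), name="arm1"),
        )
        for (a1, a2), n in dist.items():
            table.loc[a2, a1] = n
        return table

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": list(self.per_gamete_arm_counts),
                "arm1_co": [a for a, _ in self.per_gamete_arm_counts.values()],
                "arm2_co": [b for _, b in self.per_gamete_arm_counts.values()],
            }
        )


def detect_switches(
    om: OriginMatrix, mmap: MarkerMap, chromosome: int
) -> ChromosomeSwitches:
    """Walk each gamete's consecutive informative markers on one chromosome
    and record origin switches.

    Gametes with fewer than two informative markers on the chromosome are
    excluded from that chromosome (logged with a reason).
    """
    chrom = mmap.chromosome(chromosome)
    if not chrom:
        raise ValueError(f"no markers on chromosome {chromosome}")
    loci = [m.locus_id for m in chrom]
    missing_cols = [l for l in loci if l not in set(om.loci)]
    if missing_cols:
        raise ValueError(f"origin matrix lacks loci {missing_cols}")
    positions = [m.position_cm for m in chrom]
    sub = om.origins[loci]
    switches: dict[str, list[Switch]] = {}
    informative: dict[str, list[int]] = {}
    excluded: dict[str, str] = {}
    for unit, row in sub.iterrows():
        codes = row.to_numpy()
        idx = [k for k, c in enumerate(codes) if c in INFORMATIVE]
        if len(idx) < 2:
            excluded[unit] = (
                f"{len(idx)} informative marker(s) on chromosome {chromosome}"
            )
            logger.info("excluding %s: %s", unit, excluded[unit])
            continue
        informative[unit] = idx
        found = []
        for i, j in zip(idx[:-1], idx[1:]):
            if codes[i] != codes[j]:
                found.append(
                    Switch(
                        left=i,
                        right=j,
                        left_locus=loci[i],
                        right_locus=loci[j],
                        left_cm=positions[i],
                        right_cm=positions[j],
                    )
                )
        switches[unit] = found
    return ChromosomeSwitches(
        chromosome=chromosome,
        loci=loci,
        positions_cm=positions,
        switches=switches,
        informative_idx=informative,
        excluded=excluded,
    )


def _assign_arm(sw: Switch, centromere: float) -> int:
    """Arm index (1 = lower-cM arm) for a switch interval.

    An interval entirely on one side of the centromere belongs to that arm;
    a centromere-spanning interval goes to the arm holding the larger
    genetic share of the interval (exact tie -> arm 1).
    """
    if sw.right_cm <= centromere:
        return 1
    if sw.left_cm >= centromere:
        return 2
    share1 = centromere - sw.left_cm
    share2 = sw.right_cm - centromere
    return 1 if share1 >= share2 else 2


def count_per_arm(
    sw: ChromosomeSwitches, mmap: MarkerMap
) -> CrossoverSummary:
    """Assign each detected switch to a chromosome arm and summarize."""
    centromere = mmap.centromere(sw.chromosome)
    per_gamete: dict[str, tuple[int, int]] = {}
    for unit, found in sw.switches.items():
        a1 = sum(1 for s in found if _assign_arm(s, centromere) == 1)
        a2 = len(found) - a1
        per_gamete[unit] = (a1, a2)
    return CrossoverSummary(
        per_gamete_arm_counts=per_gamete, chromosome=sw.chromosome
    )


def max_crossovers(summary: CrossoverSummary) -> tuple[int, int]:
    """Per-arm maxima of the crossover counts over gametes."""
    if summary.n_gametes_analyzed == 0:
        raise ValueError("empty crossover summary")
    counts = list(summary.per_gamete_arm_counts.values())
    return max(a for a, _ in counts), max(b for _, b in counts)


def _assign_elementary(sw: Switch, positions: list[float]) -> int:
    """Elementary interval (index k = between markers k and k+1) that a
    merged-interval switch is attributed to: the covered interval with the
    largest cM length, ties to the leftmost."""
    spans = [
        (positions[k + 1] - positions[k], k) for k in range(sw.left, sw.right)
    ]
    return max(spans, key=lambda t: (t[0], -t[1]))[1]


def interval_recombination(
    om: OriginMatrix,
    mmap: MarkerMap,
    chromosome: int,
    denominator: str = "elementary",
) -> pd.DataFrame:
    """Per-interval crossover ratio n(CO)/n(M) along one chromosome.

    With the default ``elementary`` denominator, an observation between two
    informative flanks contributes to n(M) of every elementary interval it
    spans; with ``merged`` it contributes (numerator and denominator) only
    to the single elementary interval its switch would be assigned to.
    An interval with n(M) = 0 reports a NaN ratio, never 0.
    """
    if denominator not in ("elementary", "merged"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    sw = detect_switches(om, mmap, chromosome)
    m = len(sw.loci)
    if m < 2:
        raise ValueError("need at least two markers for interval analysis")
    n_co = np.zeros(m - 1, dtype=int)
    n_obs = np.zeros(m - 1, dtype=int)
    for unit in sw.analyzed_units:
        idx = sw.informative_idx[unit]
        switched = {(s.left, s.right): s for s in sw.switches[unit]}
        for i, j in zip(idx[:-1], idx[1:]):
            s = switched.get((i, j))
            if denominator == "elementary":
                n_obs[i:j] += 1
            else:
                target = (
                    _assign_elementary(s, sw.positions_cm)
                    if s is not None
                    else _assign_elementary(
                        Switch(i, j, "", "", sw.positions_cm[i], sw.positions_cm[j]),
                        sw.positions_cm,
                    )
                )
                n_obs[target] += 1
            if s is not None:
                n_co[_assign_elementary(s, sw.positions_cm)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_obs > 0, n_co / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame(
        {
            "left_locus": sw.loci[:-1],
            "right_locus": sw.loci[1:],
            "left_cm": sw.positions_cm[:-1],
            "right_cm": sw.positions_cm[1:],
            "n_co": n_co,
            "n_informative": n_obs,
            "co_ratio": ratio,
        }
    )
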