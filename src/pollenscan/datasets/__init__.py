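"""Bundled example data: the citrus marker panels, centromere positions,
published per-marker allele counts and the chromosome-1 crossover
cross-tabulation from a single-pollen genotyping study of a clementine x
sweet orange tangor ("CSO", male parent of the "RTSO" progeny) and of
"Eureka" lemon, plus simulation scenarios shaped like those populations.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..marker_io import GenotypeMatrix, MarkerMap, read_centromeres, read_marker_map
from ..origin_phasing import P1, P2
from ..synthetic_data import SimulationConfig


def _path(name: str):
    return resources.files(__package__) / "data" / name


def load_tangor_map() -> MarkerMap:
    """30-marker panel (23 SSR, 7 SNP) over the nine citrus linkage groups,
    heterozygous in the CSO tangor (parent 1) and polymorphic with the RTO
    tangor (parent 2); centromere positions included."""
    with resources.as_file(_path("tangor_markers.tsv")) as p:
        mmap = read_marker_map(p)
    with resources.as_file(_path("tangor_centromeres.tsv")) as p:
        mmap.centromere_cm = read_centromeres(p)
    return mmap


def load_lemon_map() -> MarkerMap:
    """12-marker chromosome-1 panel (7 SSR, 5 SNP) for lemon gametes.

    Lemon is an ancient sour orange x citron hybrid: parent 1 holds the
    allele assumed sour-orange-derived, parent 2 the citron-derived one
    (only the transmitted allele of each ancestor is known, stored as a
    homozygous pair; the P1 assignment to the first-noted allele is an
    assumption of this demonstration panel)."""
    with resources.as_file(_path("lemon_lg1_markers.tsv")) as p:
        mmap = read_marker_map(p)
    with resources.as_file(_path("lemon_centromeres.tsv")) as p:
        mmap.centromere_cm = read_centromeres(p)
    return mmap


def load_sd_counts() -> pd.DataFrame:
    """Published per-marker allele counts of the CSO pollen-nuclei
    population and the RTSO progeny, with the printed chi-square statistics
    and p-values (three decimals) for cross-checking."""
    with resources.as_file(_path("tangor_sd_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("locus")


def pollen_counts() -> pd.DataFrame:
    """Pollen-population counts in allele_counts layout (a1/a2 + lg/cm)."""
    df = load_sd_counts()
    return df.rename(columns={"pollen_a1": "a1", "pollen_a2": "a2"})[
        ["lg", "cm", "a1", "a2"]
    ]


def progeny_counts() -> pd.DataFrame:
    """Progeny-population counts in allele_counts layout (a1/a2 + lg/cm)."""
    df = load_sd_counts()
    return df.rename(columns={"progeny_a1": "a1", "progeny_a2": "a2"})[
        ["lg", "cm", "a1", "a2"]
    ]


def load_crossover_distribution() -> dict[tuple[int, int], int]:
    """Published chromosome-1 crossover cross-tabulation of the 34 analyzed
    lemon pollen nuclei: (arm1_count, arm2_count) -> number of gametes."""
    with resources.as_file(_path("crossover_distribution_chr1.tsv")) as p:
        df = pd.read_csv(p, sep="\t").set_index("arm2")
    out: dict[tuple[int, int], int] = {}
    for arm2, row in df.iterrows():
        for arm1, n in row.items():
            if int(n) > 0:
                out[(int(arm1), int(arm2))] = int(n)
    return out


def synthetic_lemon_qc_matrix() -> GenotypeMatrix:
    """Synthetic 44-gamete x 12-locus call matrix matching the published
    QC accounting of the lemon pollen population.

    The per-gamete raw calls were not published in machine-readable form;
    this deterministic stand-in reproduces the printed totals exactly: 34
    gametes reach the 65% positive-call threshold, and those 34 carry 362
    positive calls out of 34 x 12 = 408 attempted.  Allele content is
    arbitrary (alternating parental alleles) - only the missingness pattern
    is meaningful.
    """
    mmap = load_lemon_map()
    loci = mmap.loci
    n_loci = len(loci)
    # missing calls per gamete: 34 retained (11x4, 1x2, 22x0 -> 46 missing,
    # each rate >= 8/12 = 0.667), 10 discarded with 7 missing (rate 0.417)
    missing_per_unit = [4] * 11 + [2] + [0] * 22 + [7] * 10
    rows = {}
    for i, n_miss in enumerate(missing_per_unit):
        unit = f"Eur-P{i + 1:02d}"
        calls = []
        for j, m in enumerate(mmap.markers):
            if j < n_miss:
                calls.append(np.nan)
            else:
                pair = m.parent1_alleles if (i + j) % 2 == 0 else m.parent2_alleles
                calls.append(pair[0])
        rows[unit] = calls
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    return GenotypeMatrix(calls=frame, ploidy=1)


def tangor_pollen_config(
    seed: int, n_gametes: int = 48, dropout_rate: float = 0.033
) -> SimulationConfig:
    """CSO-pollen-like scenario: 48 gametes over the 30-marker panel,
    ~3.3% call dropout, mild gametic selection against the P1 haplotype
    around the LG2 selected locus (transmission ~ 0.35, the magnitude of
    the observed pollen distortion)."""
    return SimulationConfig(
        marker_map=load_tangor_map(),
        n_gametes=n_gametes,
        dropout_rate=dropout_rate,
        gametic_selection=[("CX6F23", 0.35)],
        seed=seed,
    )


def tangor_cross_config(
    seed: int, n_gametes: int = 86, dropout_rate: float = 0.0
) -> SimulationConfig:
    """RTSO-progeny-like scenario: the male parent's gametes carry the same
    mild LG2 gametic selection as the pollen scenario, and zygotic
    selection almost completely excludes one male haplotype class at the
    LG7 locus (the 86:0-style pattern of a gametophytic-incompatibility
    response)."""
    return SimulationConfig(
        marker_map=load_tangor_map(),
        n_gametes=n_gametes,
        dropout_rate=dropout_rate,
        gametic_selection=[("CX6F23", 0.35)],
        zygotic_selection=[("MEST202", {P1: 1.0, P2: 0.01})],
        seed=seed,
    )


def lemon_pollen_config(
    seed: int, n_gametes: int = 44, dropout_rate: float = 0.113
) -> SimulationConfig:
    """Lemon-like crossover scenario: 44 gametes on the 12-marker
    chromosome-1 panel with the observed ~11.3% call dropout; gametes are
    drawn from the sour orange x citron cross."""
    return SimulationConfig(
        marker_map=load_lemon_map(),
        n_gametes=n_gametes,
        dropout_rate=dropout_rate,
        seed=seed,
        parent="cross",
    )
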