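"""Reading and writing marker maps, genotype matrices, and gamete-level QC.

Genotype matrices hold one row per unit (a haploid pollen nucleus or a
diploid progeny individual) and one column per marker locus.  Allele labels
are opaque text: SSR fragment sizes ("204") and SNP bases ("A") share one
representation and are never coerced to numbers.  Diploid calls are
unordered pairs serialized as ``"a/b"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default sentinel for a missing allele call in delimited files.
MISSING_SENTINEL = "NA"

MAP_COLUMNS = ["locus", "lg", "cm", "class", "p1_a1", "p1_a2", "p2_a1", "p2_a2"]
MARKER_CLASSES = {"SSR", "SNP"}


class MarkerIOError(ValueError):
    """Raised for malformed marker-map or genotype files."""


@dataclass(frozen=True)
class MarkerDef:
    """One mapped marker locus.

    ``parent1_alleles`` / ``parent2_alleles`` are the noted diploid alleles
    of the two parents of the cross (for gametes of a single focal parent,
    the pair order encodes that parent's haplotype phase: index 0 =
    haplotype P1, index 1 = haplotype P2).
    """

    locus_id: str
    linkage_group: int
    position_cm: float
    marker_class: str
    parent1_alleles: tuple[str, str]
    parent2_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.position_cm < 0:
            raise MarkerIOError(
                f"{self.locus_id}: negative cM position {self.position_cm}"
            )
        if self.marker_class not in MARKER_CLASSES:
            raise MarkerIOError(
                f"{self.locus_id}: unknown marker class {self.marker_class!r}"
            )
        if not all(self.parent1_alleles) or not all(self.parent2_alleles):
            raise MarkerIOError(f"{self.locus_id}: empty allele label")


@dataclass
class MarkerMap:
    """Ordered marker panel over linkage groups, with centromere positions.

    Markers are kept sorted by (linkage group, cM position, locus id); the
    locus-id tie-break makes the order strict when simulated markers are
    co-located.
    """

    markers: list[MarkerDef]
    centromere_cm: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = sorted(
            self.markers,
            key=lambda m: (m.linkage_group, m.position_cm, m.locus_id),
        )
        seen: set[tuple[int, str]] = set()
        for m in self.markers:
            key = (m.linkage_group, m.locus_id)
            if key in seen:
                raise MarkerIOError(
                    f"duplicate locus {m.locus_id!r} on linkage group "
                    f"{m.linkage_group}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def loci(self) -> list[str]:
        return [m.locus_id for m in self.markers]

    @property
    def linkage_groups(self) -> list[int]:
        return sorted({m.linkage_group for m in self.markers})

    def chromosome(self, lg: int) -> list[MarkerDef]:
        """Markers of one linkage group, in map order."""
        return [m for m in self.markers if m.linkage_group == lg]

    def marker(self, locus_id: str) -> MarkerDef:
        for m in self.markers:
            if m.locus_id == locus_id:
                return m
        raise KeyError(locus_id)

    def centromere(self, lg: int) -> float:
        if lg not in self.centromere_cm:
            raise MarkerIOError(f"no centromere position for linkage group {lg}")
        return self.centromere_cm[lg]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": m.locus_id,
                "lg": m.linkage_group,
                "cm": m.position_cm,
                "class": m.marker_class,
                "p1_a1": m.parent1_alleles[0],
                "p1_a2": m.parent1_alleles[1],
                "p2_a1": m.parent2_alleles[0],
                "p2_a2": m.parent2_alleles[1],
            }
            for m in self.markers
        ]
        return pd.DataFrame(rows, columns=MAP_COLUMNS)


@dataclass
class GenotypeMatrix:
    """Units x loci grid of allele calls.

    ``calls`` is a pandas DataFrame of strings with NaN for missing;
    diploid calls are ``"a/b"`` with the two labels sorted.  ``off_ladder``
    marks calls whose allele label is outside the union of the parental
    alleles (kept, never silently dropped).
    """

    calls: pd.DataFrame
    ploidy: int
    off_ladder: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise MarkerIOError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.off_ladder is None:
            self.off_ladder = pd.DataFrame(
                False, index=self.calls.index, columns=self.calls.columns
            )

    @property
    def unit_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_units(self) -> int:
        return self.calls.shape[0]

    def is_missing(self) -> pd.DataFrame:
        return self.calls.isna()

    def subset(self, unit_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.loc[unit_ids].copy(),
            ploidy=self.ploidy,
            off_ladder=self.off_ladder.loc[unit_ids].copy(),
        )


@dataclass
class QCReport:
    """Per-gamete positive-amplification accounting.

    A call is "positive" when it is non-missing; the denominator for each
    unit is the full marker panel attempted for it.  ``overall_positive_rate``
    is total positive / total attempted over the *retained* units, the same
    accounting used when a study reports its positive-PCR percentage after
    discarding low-quality gametes.
    """

    per_unit_positive_rate: dict[str, float]
    retained_units: list[str]
    overall_positive_rate: float
    threshold: float
    n_loci: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_units)

    @property
    def retention_rate(self) -> float:
        return self.n_retained / len(self.per_unit_positive_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": list(self.per_unit_positive_rate),
                "positive_rate": list(self.per_unit_positive_rate.values()),
                "retained": [
                    u in set(self.retained_units)
                    for u in self.per_unit_positive_rate
                ],
            }
        )


def qc_filter(gm: GenotypeMatrix, threshold: float = 0.65) -> QCReport:
    """Retain units whose positive-call rate over the panel is >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    present = ~gm.calls.isna()
    rates = present.mean(axis=1)
    retained = list(rates.index[rates >= threshold])
    n_loci = gm.calls.shape[1]
    if retained and n_loci:
        kept = present.loc[retained]
        overall = float(kept.to_numpy().sum()) / float(kept.size)
    else:
        overall = float("nan")
    return QCReport(
        per_unit_positive_rate={u: float(r) for u, r in rates.items()},
        retained_units=retained,
        overall_positive_rate=overall,
        threshold=threshold,
        n_loci=n_loci,
    )


# ---------------------------------------------------------------------------
# delimited-text IO


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


def read_marker_map(
    path,
    dialect: str = "tsv",
    centromere_path=None,
) -> MarkerMap:
    """Read a marker map table (columns ``locus lg cm class p1_a1 p1_a2
    p2_a1 p2_a2``) and optionally a centromere table (``lg cm``)."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    missing_cols = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise MarkerIOError(f"{path}: missing required columns {missing_cols}")
    markers = []
    for _, row in df.iterrows():
        try:
            lg = int(row["lg"])
            cm = float(row["cm"])
        except (TypeError, ValueError) as exc:
            raise MarkerIOError(
                f"{path}: non-numeric lg/cM for locus {row['locus']!r}"
            ) from exc
        markers.append(
            MarkerDef(
                locus_id=str(row["locus"]),
                linkage_group=lg,
                position_cm=cm,
                marker_class=str(row["class"]),
                parent1_alleles=(str(row["p1_a1"]), str(row["p1_a2"])),
                parent2_alleles=(str(row["p2_a1"]), str(row["p2_a2"])),
            )
        )
    centromeres: dict[int, float] = {}
    if centromere_path is not None:
        centromeres = read_centromeres(centromere_path, dialect=dialect)
    return MarkerMap(markers=markers, centromere_cm=centromeres)


def read_centromeres(path, dialect: str = "tsv") -> dict[int, float]:
    df = pd.read_csv(path, sep=_sep(dialect))
    if not {"lg", "cm"} <= set(df.columns):
        raise MarkerIOError(f"{path}: centromere file needs columns lg, cm")
    return {int(r["lg"]): float(r["cm"]) for _, r in df.iterrows()}


def write_marker_map(mmap: MarkerMap, path, dialect: str = "tsv") -> None:
    mmap.to_frame().to_csv(path, sep=_sep(dialect), index=False)


def write_centromeres(centromeres: dict[int, float], path, dialect="tsv") -> None:
    pd.DataFrame(
        {"lg": list(centromeres), "cm": list(centromeres.values())}
    ).to_csv(path, sep=_sep(dialect), index=False)


def _parental_allele_union(marker: MarkerDef) -> set[str]:
    return set(marker.parent1_alleles) | set(marker.parent2_alleles)


def _normalize_diploid(call: str) -> str:
    parts = call.split("/")
    if len(parts) == 1:  # single peak recorded: treat as homozygous
        parts = [parts[0], parts[0]]
    if len(parts) != 2:
        raise MarkerIOError(f"malformed diploid call {call!r}")
    return "/".join(sorted(parts))


def read_genotypes(
    path,
    mmap: MarkerMap,
    ploidy: int,
    dialect: str = "tsv",
    missing: str = MISSING_SENTINEL,
    ignore_unknown_loci: bool = False,
) -> GenotypeMatrix:
    """Read a genotype matrix; first column = unit id, remaining = loci.

    Columns are matched to the map order-insensitively and the result is
    ordered as in the map.  Calls whose allele label falls outside the
    parental alleles are accepted but flagged off-ladder with a warning.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0])
    unknown = [c for c in df.columns if c not in set(mmap.loci)]
    if unknown and not ignore_unknown_loci:
        raise MarkerIOError(f"{path}: columns not in marker map: {unknown}")
    absent = [l for l in mmap.loci if l not in set(df.columns)]
    if absent:
        raise MarkerIOError(f"{path}: map loci missing from matrix: {absent}")
    df = df[mmap.loci]
    df = df.where(~df.isin([missing, ""]))
    return build_genotype_matrix(df, mmap, ploidy)


def build_genotype_matrix(
    calls: pd.DataFrame, mmap: MarkerMap, ploidy: int
) -> GenotypeMatrix:
    """Validate a raw string call frame against the map and flag off-ladder
    alleles.  Haploid matrices reject ``a/b`` pairs outright."""
    calls = calls.copy()
    off = pd.DataFrame(False, index=calls.index, columns=calls.columns)
    for m in mmap.markers:
        col = calls[m.locus_id]
        known = _parental_allele_union(m)
        for unit, val in col.items():
            if pd.isna(val):
                continue
            val = str(val)
            if ploidy == 1:
                if "/" in val:
                    raise MarkerIOError(
                        f"diploid call {val!r} at {m.locus_id} in haploid matrix"
                    )
                if val not in known:
                    off.loc[unit, m.locus_id] = True
            else:
                norm = _normalize_diploid(val)
                calls.loc[unit, m.locus_id] = norm
                if any(a not in known for a in norm.split("/")):
                    off.loc[unit, m.locus_id] = True
    n_off = int(off.to_numpy().sum())
    if n_off:
        warnings.warn(
            f"{n_off} call(s) carry alleles outside the parental ladder; "
            "kept and flagged off-ladder",
            stacklevel=2,
        )
    return GenotypeMatrix(calls=calls, ploidy=ploidy, off_ladder=off)


def write_genotypes(
    gm: GenotypeMatrix, path, dialect: str = "tsv", missing: str = MISSING_SENTINEL
) -> None:
    out = gm.calls.fillna(missing)
    out.index.name = "unit_id"
    out.to_csv(path, sep=_sep(dialect))


def write_table(result, path, dialect: str = "tsv") -> None:
    """Write any tabular result (DataFrame or object with .to_frame()) as
    delimited text; round-trips text and integer columns exactly."""
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    frame.to_csv(path, sep=_sep(dialect), index=False)


def read_table(path, dialect: str = "tsv") -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(dialect))
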