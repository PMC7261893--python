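"""Parental-origin assignment for haploid gamete genotypes.

Each allele call of a gamete is translated into the haplotype of the focal
parent it was inherited from: ``P1`` or ``P2`` (e.g. the sour-orange- and
citron-derived homologs of a lemon).  Calls that cannot be assigned stay
``MISSING`` (no amplification), ``AMBIGUOUS`` (allele present on both
haplotypes, uninformative marker) or ``OFF_LADDER`` (allele outside the
parental ladder).  Downstream crossover counting treats everything except
P1/P2 as uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .marker_io import GenotypeMatrix, MarkerMap, MarkerIOError, _sep

P1 = "P1"
P2 = "P2"
MISSING = "MISSING"
AMBIGUOUS = "AMBIGUOUS"
OFF_LADDER = "OFF_LADDER"
ORIGIN_CODES = (P1, P2, MISSING, AMBIGUOUS, OFF_LADDER)
INFORMATIVE = (P1, P2)

#: locus -> allele -> P1 | P2 | AMBIGUOUS
PhaseTable = dict[str, dict[str, str]]


@dataclass
class OriginMatrix:
    """Units x loci grid of parental-origin codes (same shape as the source
    genotype matrix)."""

    origins: pd.DataFrame

    @property
    def unit_ids(self) -> list[str]:
        return list(self.origins.index)

    @property
    def loci(self) -> list[str]:
        return list(self.origins.columns)

    def informative_mask(self) -> pd.DataFrame:
        return self.origins.isin(INFORMATIVE)

    def to_frame(self) -> pd.DataFrame:
        out = self.origins.copy()
        out.insert(0, "unit_id", out.index)
        return out.reset_index(drop=True)


def phase_from_map(mmap: MarkerMap, parent: int = 1) -> PhaseTable:
    """Phase table from a marker map's allele pair order.

    The focal parent's pair is read as (haplotype-P1 allele, haplotype-P2
    allele); an allele shared by both haplotypes maps to AMBIGUOUS.
    """
    phase: PhaseTable = {}
    for m in mmap.markers:
        pair = m.parent1_alleles if parent == 1 else m.parent2_alleles
        a1, a2 = pair
        if a1 == a2:
            phase[m.locus_id] = {a1: AMBIGUOUS}
        else:
            phase[m.locus_id] = {a1: P1, a2: P2}
    return phase


def phase_from_parents(mmap: MarkerMap) -> PhaseTable:
    """Phase table for gametes of an F1 between the map's two parents:
    an allele found only among parent-1 alleles maps to P1, only among
    parent-2 alleles to P2, and a shared allele to AMBIGUOUS (the lemon
    case, where P1 = sour-orange-derived and P2 = citron-derived)."""
    phase: PhaseTable = {}
    for m in mmap.markers:
        s1, s2 = set(m.parent1_alleles), set(m.parent2_alleles)
        entry: dict[str, str] = {}
        for allele in s1 | s2:
            if allele in s1 and allele in s2:
                entry[allele] = AMBIGUOUS
            else:
                entry[allele] = P1 if allele in s1 else P2
        phase[m.locus_id] = entry
    return phase


def read_phase(path, dialect: str = "tsv") -> PhaseTable:
    """Read an explicit phase file with columns ``locus allele haplotype``
    (haplotype P1 or P2); an allele listed under both haplotypes becomes
    AMBIGUOUS."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    if not {"locus", "allele", "haplotype"} <= set(df.columns):
        raise MarkerIOError(f"{path}: phase file needs locus, allele, haplotype")
    phase: PhaseTable = {}
    for _, row in df.iterrows():
        hap = row["haplotype"]
        if hap not in (P1, P2):
            raise MarkerIOError(f"{path}: haplotype must be P1/P2, got {hap!r}")
        locus = phase.setdefault(str(row["locus"]), {})
        allele = str(row["allele"])
        if allele in locus and locus[allele] != hap:
            locus[allele] = AMBIGUOUS
        else:
            locus[allele] = hap
    return phase


def write_phase(phase: PhaseTable, path, dialect: str = "tsv") -> None:
    rows = []
    for locus, alleles in phase.items():
        for allele, hap in alleles.items():
            haps = (P1, P2) if hap == AMBIGUOUS else (hap,)
            rows.extend(
                {"locus": locus, "allele": allele, "haplotype": h} for h in haps
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect), index=False)


def swap_phase(phase: PhaseTable) -> PhaseTable:
    """Exchange the P1/P2 labels of every allele (relabeling symmetry)."""
    flip = {P1: P2, P2: P1, AMBIGUOUS: AMBIGUOUS}
    return {
        locus: {a: flip[h] for a, h in alleles.items()}
        for locus, alleles in phase.items()
    }


def assign_origin(
    gm: GenotypeMatrix, mmap: MarkerMap, phase: PhaseTable
) -> OriginMatrix:
    """Map each haploid allele call to the parental haplotype it matches.

    A call maps to P1/P2 only when the observed allele matches exactly one
    parental haplotype; alleles absent from the phase table's ladder are
    OFF_LADDER.
    """
    if gm.ploidy != 1:
        raise ValueError("assign_origin expects a haploid genotype matrix")
    cols = {}
    for locus in gm.loci:
        if locus not in phase:
            raise MarkerIOError(f"locus {locus!r} absent from phase table")
        lookup = phase[locus]
        col = gm.calls[locus]
        out = col.map(lambda v: lookup.get(v, OFF_LADDER), na_action="ignore")
        cols[locus] = out.fillna(MISSING)
    origins = pd.DataFrame(cols, index=gm.calls.index)[gm.loci]
    return OriginMatrix(origins=origins)


def informativeness_report(om: OriginMatrix) -> pd.DataFrame:
    """Per-locus fractions of each origin code (rows sum to 1)."""
    rows = []
    n = len(om.unit_ids)
    for locus in om.loci:
        counts = om.origins[locus].value_counts()
        row = {"locus": locus}
        for code in ORIGIN_CODES:
            row[code] = float(counts.get(code, 0)) / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
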