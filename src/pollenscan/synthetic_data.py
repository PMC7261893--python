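"""Meiosis simulator: haploid gamete and diploid progeny populations.

The generator produces data with the statistical structure the analysis
stages assume: parental origin along each chromosome follows a Markov chain
over the ordered markers (no crossover interference), with switch
probabilities given by a mapping function (Haldane or Kosambi) applied to
the inter-marker cM distances.  Gametic selection (transmission-ratio
distortion before fertilization) is imposed by rejection sampling on the
realized allele at selected loci; zygotic selection thins male x female
gamete pairs by a survival probability keyed on the male-transmitted
haplotype class.  Whole-genome-amplification noise is modelled as i.i.d.
per-call dropout.

All randomness flows from a single integer seed, expanded into independent
substreams (one per population/process) via numpy's SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_io import GenotypeMatrix, MarkerMap
from .origin_phasing import P1, P2

MAPPING_FUNCTIONS = ("haldane", "kosambi")
_MAX_REJECTION_ROUNDS = 1000


class SimulationError(RuntimeError):
    pass


def recomb_fraction(d_cm, fn: str = "haldane"):
    """Recombination fraction for a map distance in centiMorgans.

    Haldane: r = (1 - exp(-2d)) / 2;  Kosambi: r = tanh(2d) / 2, with d in
    Morgans.  Both satisfy 0 <= r < 1/2 and r -> 1/2 as d grows.
    """
    d = np.asarray(d_cm, dtype=float) / 100.0
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    if fn == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
    elif fn == "kosambi":
        r = 0.5 * np.tanh(2.0 * d)
    else:
        raise ValueError(f"unknown mapping function {fn!r}")
    return float(r) if np.isscalar(d_cm) else r


@dataclass
class GameteTruth:
    """Ground truth for one simulated gamete: the parental origin at every
    marker (in map order) and the cM positions of the realized crossovers
    per linkage group.  Origin switches between adjacent markers iff an odd
    number of crossover positions falls in the interval (here 0 or 1, since
    the chain draws at most one crossover per marker interval)."""

    origin_codes: np.ndarray  # of "P1"/"P2", aligned with map loci
    crossover_positions: dict[int, tuple[float, ...]]


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated gamete population.

    gametic_selection: [(locus_id, t)] with t = transmission probability of
    the parent-1-haplotype allele at that locus (t = 0.5 is Mendelian).
    zygotic_selection: [(locus_id, {"P1": s1, "P2": s2})] with survival
    probabilities of a progeny keyed on the male-transmitted haplotype.
    """

    marker_map: MarkerMap
    n_gametes: int
    mapping_function: str = "haldane"
    gametic_selection: list[tuple[str, float]] = field(default_factory=list)
    zygotic_selection: list[tuple[str, dict[str, float]]] = field(
        default_factory=list
    )
    dropout_rate: float = 0.0
    seed: int = 0
    #: which parent produces the gametes: 1 or 2 (pair order encodes that
    #: parent's haplotype phase) or "cross" for gametes of the F1 between
    #: the map's two parents (P1 allele = parent1's transmitted allele).
    parent: int | str = 1

    def __post_init__(self) -> None:
        if self.n_gametes <= 0:
            raise ValueError("n_gametes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.mapping_function not in MAPPING_FUNCTIONS:
            raise ValueError(f"unknown mapping function {self.mapping_function!r}")
        if self.parent not in (1, 2, "cross"):
            raise ValueError(f"parent must be 1, 2 or 'cross', got {self.parent!r}")
        loci = set(self.marker_map.loci)
        for locus, t in self.gametic_selection:
            if locus not in loci:
                raise ValueError(f"gametic selection locus {locus!r} not in map")
            if not 0 <= t <= 1:
                raise ValueError(f"transmission probability out of range: {t}")
        for locus, probs in self.zygotic_selection:
            if locus not in loci:
                raise ValueError(f"zygotic selection locus {locus!r} not in map")
            for cls, s in probs.items():
                if cls not in (P1, P2):
                    raise ValueError(f"unknown progeny class {cls!r}")
                if not 0 <= s <= 1:
                    raise ValueError(f"survival probability out of range: {s}")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_origin_block(
    mmap: MarkerMap, n: int, fn: str, rng: np.random.Generator
):
    """Draw origins for n gametes over all linkage groups.

    Returns (is_p2: bool array n x L in map order,
             xo_pos: dict lg -> list over gametes of crossover-position arrays).
    """
    loci = mmap.loci
    is_p2 = np.empty((n, len(loci)), dtype=bool)
    xo_pos: dict[int, list[np.ndarray]] = {}
    col = 0
    for lg in mmap.linkage_groups:
        chrom = mmap.chromosome(lg)
        m = len(chrom)
        block = np.empty((n, m), dtype=bool)
        block[:, 0] = rng.random(n) < 0.5
        pos = np.array([mk.position_cm for mk in chrom])
        if m > 1:
            r = recomb_fraction(np.diff(pos), fn)
            switches = rng.random((n, m - 1)) < r[None, :]
            # cumulative XOR of switch indicators along the chromosome
            block[:, 1:] = block[:, [0]] ^ (np.cumsum(switches, axis=1) % 2 == 1)
            u = rng.random((n, m - 1))
            locs = pos[:-1][None, :] + u * np.diff(pos)[None, :]
            xo_pos[lg] = [locs[i][switches[i]] for i in range(n)]
        else:
            xo_pos[lg] = [np.empty(0) for _ in range(n)]
        is_p2[:, col : col + m] = block
        col += m
    return is_p2, xo_pos


def _acceptance_probability(
    cfg: SimulationConfig, is_p2: np.ndarray
) -> np.ndarray:
    """Relative acceptance probability per gamete under gametic selection,
    normalized so the most favoured class has probability 1."""
    p = np.ones(is_p2.shape[0])
    loci = cfg.marker_map.loci
    for locus, t in cfg.gametic_selection:
        j = loci.index(locus)
        w = np.where(is_p2[:, j], 1.0 - t, t)
        p *= w / max(t, 1.0 - t)
    return p


def _origins_with_selection(cfg: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample gametes until n accepted; bounded rounds guard
    against contradictory degenerate selection (e.g. t=1 and t=0 at one
    locus)."""
    n = cfg.n_gametes
    kept_origin: list[np.ndarray] = []
    kept_xo: list[dict[int, np.ndarray]] = []
    rounds = 0
    while sum(b.shape[0] for b in kept_origin) < n:
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise SimulationError(
                "gametic-selection rejection sampling failed to accept enough "
                "gametes; selection constraints may be contradictory"
            )
        batch = max(n, 64)
        is_p2, xo = _simulate_origin_block(
            cfg.marker_map, batch, cfg.mapping_function, rng
        )
        accept = rng.random(batch) < _acceptance_probability(cfg, is_p2)
        idx = np.flatnonzero(accept)
        kept_origin.append(is_p2[idx])
        kept_xo.extend(
            {lg: arrs[i] for lg, arrs in xo.items()} for i in idx
        )
    is_p2 = np.vstack(kept_origin)[:n]
    return is_p2, kept_xo[:n]


def _calls_from_origins(
    mmap: MarkerMap, is_p2: np.ndarray, parent: int
) -> np.ndarray:
    """Translate origins into allele labels using the parental phase encoded
    by the map's allele-pair order."""
    n, m = is_p2.shape
    calls = np.empty((n, m), dtype=object)
    for j, mk in enumerate(mmap.markers):
        if parent == "cross":
            pair = (mk.parent1_alleles[0], mk.parent2_alleles[0])
        else:
            pair = mk.parent1_alleles if parent == 1 else mk.parent2_alleles
        calls[:, j] = np.where(is_p2[:, j], pair[1], pair[0])
    return calls


def _truths(mmap: MarkerMap, is_p2, xo_list) -> list[GameteTruth]:
    codes = np.where(is_p2, P2, P1)
    return [
        GameteTruth(
            origin_codes=codes[i],
            crossover_positions={
                lg: tuple(float(x) for x in xo_list[i][lg])
                for lg in xo_list[i]
            },
        )
        for i in range(is_p2.shape[0])
    ]


def simulate_gametes(
    cfg: SimulationConfig, unit_prefix: str = "G"
) -> tuple[GenotypeMatrix, list[GameteTruth]]:
    """Simulate a haploid gamete population with optional gametic selection
    and dropout; returns the (noisy) genotype matrix and per-gamete truth."""
    rng_origin, rng_drop = _streams(cfg.seed, 5)[:2]
    is_p2, xo_list = _origins_with_selection(cfg, rng_origin)
    calls = _calls_from_origins(cfg.marker_map, is_p2, cfg.parent)
    ids = [f"{unit_prefix}{i + 1:04d}" for i in range(cfg.n_gametes)]
    frame = pd.DataFrame(calls, index=ids, columns=cfg.marker_map.loci)
    gm = GenotypeMatrix(calls=frame, ploidy=1)
    if cfg.dropout_rate > 0:
        gm = _dropout(gm, cfg.dropout_rate, rng_drop)
    return gm, _truths(cfg.marker_map, is_p2, xo_list)


def apply_dropout(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each non-missing call MISSING independently with the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    return _dropout(gm, rate, np.random.default_rng(seed))


def _dropout(
    gm: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    calls = gm.calls.copy()
    mask = (rng.random(calls.shape) < rate) & ~calls.isna().to_numpy()
    calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns))
    return GenotypeMatrix(calls=calls, ploidy=gm.ploidy, off_ladder=gm.off_ladder)


@dataclass
class ProgenySimulation:
    """Outcome of one simulated cross: the surviving diploid progeny, the
    pre-fertilization male gamete pool (all male gametes after gametic but
    before zygotic selection), and the male truths in pool order."""

    progeny: GenotypeMatrix
    male_pool: GenotypeMatrix
    male_truths: list[GameteTruth]
    survivor_index: np.ndarray


def simulate_progeny(
    cfg: SimulationConfig,
    female_gametes: GenotypeMatrix | None = None,
) -> ProgenySimulation:
    """Simulate a diploid progeny population from cfg's male parent.

    Female gametes are either supplied (haploid matrix over the same loci)
    or simulated from the map's parent 2 with Mendelian segregation.  Each
    male gamete i is paired with female gamete i; the pair survives with
    the product of the zygotic survival probabilities of the male-origin
    classes at the selected loci.
    """
    if cfg.parent == "cross":
        raise ValueError("simulate_progeny needs a parental (1 or 2) gamete source")
    rngs = _streams(cfg.seed, 5)
    rng_male, rng_female, rng_zyg, _, rng_drop = rngs
    is_p2, xo_list = _origins_with_selection(cfg, rng_male)
    male_calls = _calls_from_origins(cfg.marker_map, is_p2, cfg.parent)
    n_male = cfg.n_gametes

    if female_gametes is None:
        f_is_p2, _ = _simulate_origin_block(
            cfg.marker_map, n_male, cfg.mapping_function, rng_female
        )
        female_calls = _calls_from_origins(
            cfg.marker_map, f_is_p2, 2 if cfg.parent == 1 else 1
        )
    else:
        if list(female_gametes.loci) != list(cfg.marker_map.loci):
            raise ValueError("female gamete loci do not match the marker map")
        female_calls = female_gametes.calls.to_numpy(dtype=object)

    n_pairs = min(n_male, female_calls.shape[0])
    loci = cfg.marker_map.loci
    survival = np.ones(n_pairs)
    for locus, probs in cfg.zygotic_selection:
        j = loci.index(locus)
        cls = np.where(is_p2[:n_pairs, j], P2, P1)
        survival *= np.array([probs.get(c, 1.0) for c in cls])
    keep = np.flatnonzero(rng_zyg.random(n_pairs) < survival)
    if keep.size == 0:
        raise SimulationError(
            "no progeny survived zygotic selection; increase n_gametes or "
            "relax survival probabilities"
        )

    rows = np.empty((keep.size, len(loci)), dtype=object)
    for k, i in enumerate(keep):
        for j in range(len(loci)):
            a, b = male_calls[i, j], female_calls[i, j]
            if a is None or b is None or pd.isna(a) or pd.isna(b):
                rows[k, j] = np.nan
            else:
                rows[k, j] = "/".join(sorted([str(a), str(b)]))
    prog_ids = [f"H{i + 1:04d}" for i in range(keep.size)]
    progeny = GenotypeMatrix(
        calls=pd.DataFrame(rows, index=prog_ids, columns=loci), ploidy=2
    )
    pool_ids = [f"G{i + 1:04d}" for i in range(n_male)]
    male_pool = GenotypeMatrix(
        calls=pd.DataFrame(male_calls, index=pool_ids, columns=loci), ploidy=1
    )
    if cfg.dropout_rate > 0:
        progeny = _dropout(progeny, cfg.dropout_rate, rng_drop)
        male_pool = _dropout(male_pool, cfg.dropout_rate, rng_drop)
    return ProgenySimulation(
        progeny=progeny,
        male_pool=male_pool,
        male_truths=_truths(cfg.marker_map, is_p2, xo_list),
        survivor_index=keep,
    )
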