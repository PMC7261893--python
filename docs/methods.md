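# Methods

## Data model

A **marker map** is an ordered panel of loci, each with a linkage group
(LG), a cM position on the reference genetic map, a marker class (SSR or
SNP) and the noted diploid alleles of the two parents of the cross.
Allele labels are opaque text: SSR fragment sizes and SNP bases share one
representation and are never coerced to numbers. Within an LG markers are
sorted by cM with a stable locus-id tie-break, so co-located simulated
markers have a deterministic order. Centromere positions (cM per LG) are a
separate input; the bundled citrus panels carry centromeres derived from
each marker's distance-to-centromere column, which is consistent across
all markers of an LG.

A **genotype matrix** is units x loci with `NA` (configurable sentinel,
empty string also accepted) for missing calls; diploid calls are
unordered pairs serialized `a/b`. Calls whose allele is outside the union
of parental alleles are kept but flagged *off-ladder* — real capillary
data contain such calls and silently dropping them would bias QC.

## Gamete QC

The per-gamete positive rate is (non-missing calls) / (panel size); the
full panel is always the denominator, including loci that failed in every
gamete. Gametes at or above the threshold (default 0.65) are retained.
The report's overall positive rate is total positive / total attempted
*over retained gametes*: that is the accounting that matches how such
studies report their positive-PCR percentages after discarding bad wells,
and it equals the mean per-gamete rate whenever all gametes attempt the
same panel.

## Origin phasing

Phase is an explicit input, not inferred. Two constructions cover the two
study designs:

- `phase_from_map(map, parent)` — gametes of one diploid parent; the
  parent's allele-pair order encodes its haplotype phase (index 0 = P1).
- `phase_from_parents(map)` — gametes of an F1 between the map's two
  parents (the lemon case: P1 = sour-orange-derived allele, P2 =
  citron-derived); an allele present in both parents maps to AMBIGUOUS.

Calls map to P1/P2 only when the allele matches exactly one haplotype;
AMBIGUOUS and OFF_LADDER are treated exactly like MISSING downstream (the
"pairs of markers with missing data are omitted" rule covers any
uninformative point). Swapping the P1/P2 labels swaps every informative
cell and changes no count anywhere downstream (tested property).

## Crossover counting

For each gamete and chromosome we walk consecutive *informative* markers;
a change of origin is one crossover, recorded on the interval between the
two informative flanks (which may span skipped loci). Double crossovers
inside one interval are undetectable, so a switch counts as exactly 1 and
the detected pattern equals the parity of the true crossover count per
interval — the simulator-backed oracle test asserts this exactly at
dropout 0. A gamete enters a chromosome's summary when it has >= 2
informative markers there; excluded gametes are logged with the reason.

Arm assignment: an interval entirely on one side of the centromere
belongs to that arm; a centromere-spanning interval goes to the arm with
the larger genetic share of the interval, exact ties to arm 1 (arm 1 =
lower-cM arm). The published cross-tabulation cannot adjudicate a
spanning rule, so this is a documented convention.

Interval recombination: for every elementary adjacent-marker interval,
`co_ratio = n(CO) / n(M)`. Under the default `elementary` denominator an
observation between informative flanks contributes to n(M) of every
elementary interval it spans, and its switch (if any) to the single
spanned interval with the largest cM width (ties leftmost) — this keeps
the conservation law sum over intervals of n(CO) = total detected
switches. A `merged` variant assigns the whole observation to that single
interval instead; both are exposed because the field's denominator
convention is genuinely ambiguous. An interval with n(M) = 0 reports NaN,
never 0.

## Segregation-distortion scan

Per marker, `chi2 = (a1 - a2)^2 / (a1 + a2)` against the 1:1 gametic
expectation, p from the chi-square upper tail with 1 df, **no continuity
correction** — the uncorrected statistic reproduces the published values
exactly (e.g. 21:26 -> 0.532). Markers are declared distorted at p <
alpha (default 0.05) with **no multiplicity adjustment**, matching
standard practice in linkage-map distortion scans; Bonferroni/BH are
available behind a flag, off by default.

Progeny counts decompose each diploid call against the two parents by
brute force over the 2x2 allele assignments: if exactly one decomposition
is valid the male allele is counted; if both are valid (both observed
alleles occur in both parents) the unit is excluded as ambiguous with an
audit count. On panels chosen for unequivocal parental differentiation
this set is empty. The same decomposition yields the male-haplotype
matrix used for the joint diversity tree.

SDRs are maximal runs of >= `min_run` (default 2) consecutive distorted
markers on one LG — distortion clusters around a selected locus because
linked markers hitchhike.

## Meiosis simulator

Per chromosome, parental origin along the ordered markers is a Markov
chain: the first marker is P1/P2 with probability 1/2 and the origin
switches between adjacent markers with probability `r(d)` from the
mapping function — Haldane `r = (1 - exp(-2d))/2` (no interference,
the default) or Kosambi `r = tanh(2d)/2`, d in Morgans. The chain draws at
most one crossover per marker interval (position uniform within the
interval), so simulated crossover counts are map-resolution-limited; the
observed-count distribution is a qualitative surface, not a calibrated
one, because no interference model is assumed.

- **Gametic selection** `(locus, t)`: rejection sampling keyed on the
  realized haplotype at the locus — P1 carriers are accepted with
  probability proportional to `t`, P2 with `1 - t`, so the accepted pool
  transmits P1 with probability t. Several selected loci apply jointly;
  hitchhiking at linked markers emerges from the origin chain rather than
  being modelled. Contradictory degenerate constraints (t = 1 and t = 0 at
  one locus) exhaust a bounded number of rejection rounds and raise.
- **Zygotic selection** `(locus, {P1: s1, P2: s2})`: male gamete i is
  paired with female gamete i (supplied, or simulated Mendelian from the
  other parent) and the pair survives with the product of the survival
  probabilities of its male-transmitted class at each selected locus.
  The pre-fertilization male pool is returned alongside the surviving
  progeny, which is exactly the contrast that separates gametic from
  zygotic selection.
- **Dropout**: each non-missing call is masked i.i.d. with the dropout
  rate — a single uniform process; locus-specific WGA bias is not
  modelled (no published rates to calibrate it).

One integer seed expands into independent substreams (male origins,
female origins, zygotic thinning, dropout) via numpy `SeedSequence`
spawning; fixed seed gives bit-identical outputs.

Bundled scenarios mirror the study conditions: a 48-gamete pollen
population on the 30-marker panel with 3.3% dropout and mild gametic
selection on LG 2 (t = 0.35, the magnitude of the observed pollen skew); an
86-progeny cross with the same gametic selection plus near-complete
zygotic exclusion of one male class at the LG 7 locus (the 86:0 pattern);
and a 44-gamete lemon population on the chromosome-1 panel with 11.3%
dropout. What passing simulator-backed tests show is that the *analysis*
is correct under these assumptions; real WGA data additionally contain
locus-specific dropout, allele drop-in and interference, none of which
the generator produces.

## Diversity

Simple matching at ploidy 1: `d(i,j) = 1 - matches / L` with pairwise
deletion (L = jointly non-missing loci of the pair, reported alongside
d). A pair with L = 0 has no defined distance and raises unless NaN is
explicitly allowed. With complete data d is the normalized Hamming
distance (cross-checked in tests).

Neighbor joining is the classic Saitou–Nei agglomeration (Q criterion,
standard branch lengths). A negative branch length is clamped to 0 with
its magnitude transferred to the sister branch, preserving the joined
pair's distance. Q ties break on the smallest leaf name under each
candidate pair, making the tree invariant to input row order even when
duplicate genotypes give exact ties. The unrooted tree is serialized as
Newick (branch lengths to 6 decimals) rooted arbitrarily at the final
3-way join. The "weighted" NJ variant used by some desktop packages is
deliberately approximated by classic NJ (with a warning): its
variance-weighted joining is out of scope, and all topology guarantees
are stated for the classic variant. On additive matrices the tree's
leaf-to-leaf path lengths reproduce the input to < 1e-9 (tested, and
cross-checked against scikit-bio's implementation).

The two-population report concatenates the pollen matrix with the
male-haplotype matrix extracted from progeny, labels leaves by source and
counts maximal single-population subtrees (>= 2 leaves by default) under
the serialization rooting — a simple, deterministic proxy for
population-exclusive clusters.

## Numerical and calibration choices

- Chi-square p-values come from `scipy.stats.chi2.sf`; published tables
  that round p to 3 decimals can disagree in the last digit, so exactness
  tests compare statistics at 3 decimals and p within 0.001.
- The type-I-error calibration of the scan uses 250 populations of 250
  gametes at nine unlinked markers (2250 replicate tests). At ~50 gametes
  the exact size of the test oscillates between 0.04 and 0.06 with
  binomial discreteness; 250 gametes is the package's chosen calibration
  size where the nominal 5% level is attained (exact size 0.0497), so the
  Monte-Carlo confidence interval is a meaningful check of the
  implementation rather than of discreteness.
- Parameter-recovery checks run at 5000 gametes, where the per-interval
  binomial standard error is small enough to detect implementation bias.
- Statistical assertions in the test suite are seeded and use 3-4 SD /
  95% CI tolerances; they validate structure (unbiasedness, calibration,
  parity), not published effect sizes.

## Known limitations

- No crossover interference (gamma/counting models), chromatid
  interference, or unreduced (2n) gamete simulation.
- Dropout is uniform across loci and gametes.
- Double crossovers within a marker interval are invisible by design of
  the observable; reported crossover counts are lower bounds at the map's
  marker resolution.
- The weighted-NJ variant is an alias for classic NJ.
- Phase of the focal parent is an input; the package does not infer it
  from the gamete population.
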