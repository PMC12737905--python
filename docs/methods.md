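# Methods

## The segregation model

Each chromosome-set segment of a tetraploid individual carries
`a` copies from subgenome A and `b = 4 - a` from subgenome B. Meiosis
transmits two of the four copies per gamete:

- **Disomic pairing** (strict homolog pairing): defined only for
  balanced segments (`a = 2`); each gamete carries exactly one A and
  one B, so the dosage never changes.
- **Tetrasomic pairing** (multivalent / homoeologous): the gamete is a
  uniform 2-subset of the four copies, so its A-count is
  hypergeometric(4, a, 2). Unbalanced dosages (`a` odd) cannot pair
  disomically and always segregate this way.

A balanced segment forms a multivalent with probability `p_he`
*independently in each meiosis* (the two gametes of a selfing event
come from different meioses). Offspring dosage is the sum of two
independent gamete draws. Consequences used throughout the package and
its tests:

- Selfing from dosage 3 yields offspring {2: 1/4, 3: 1/2, 4: 1/4}
  (convolution of the gamete law [1/2, 1/2] on {1, 2}).
- Dosages 0 and 4 are absorbing: once a segment is AAAA or BBBB it is
  fixed in a selfing lineage.
- Mean dosage is a martingale, so for any `p_he > 0` a dosage-`d`
  segment ultimately fixes AAAA with probability `d/4`
  (`fixation_probability` solves the chain exactly; the Monte-Carlo
  check in the tests agrees within sampling error).

Breakpoints (new segment boundaries) arrive Poisson(`breakpoint_rate`)
per chromosome set per generation at uniform positions, before
segregation. No recombination map is imposed — positions are uniform
because no finer information is available, and segment dosage, not
crossover interference, is the object of interest.

Aneuploidy is kept separate from `p_he`: a per-generation,
per-chromosome-set nondisjunction probability (default 0) makes one
gamete transmit one copy more or fewer. Aneuploid segments (3, 5 or 6
total copies) segregate by hypergeometric draws of the appropriate
gamete size, so they can revert toward euploidy. The default is zero
because observed aneuploids are real but rare and no rate is
measurable from small lineage panels; analyses that need aneuploid
chromosomes construct them explicitly.

Lineages are advanced by single-seed descent (one offspring per
parent), matching how such greenhouse populations are actually run.
All randomness flows from one integer seed through
`numpy.random.SeedSequence`, so every table is reproducible.

## Sequencing model and dosage inference

Read counts at diagnostic AB sites are modeled as
`depth ~ Poisson(mean_cov * total_copies / 4)` with
`A ~ Binomial(depth, a / total)`. This is deliberately unbiased: no
mapping bias, GC effect or error model. Real data show a slight
systematic underestimation of normalized A counts attributable to
mapping bias; the simulator must *not* reproduce it, and the tests
assert the normalized means converge exactly to the expected profiles
at high coverage. Passing tests therefore demonstrate correctness of
the inference machinery, not robustness to alignment artifacts.

Normalization is the ratio-of-ratios

```
normalizedA = (sampleAcount / sample mean coverage)
              / (normrefAcount / normref mean coverage)
```

against a synthetic 1:1 A:B reference read set, giving expectation
`copies / 2` (AABB → (1, 1), AAAB → (1.5, 0.5), AAAAB → (2, 0.5)).
Sample mean coverage is the mean site depth over all diagnostic sites
— note this makes the genome-wide composition part of the scale: a
genome that is mostly balanced (as real ones are) keeps the scale at
1, which is why the recovery experiments embed each tested state in a
mostly-AABB genome. Sites with a zero reference count are flagged
missing, never divided.

Windows are defined by **site count** (default `window_n = 200`), not
by physical span, so sparse regions keep statistical power; the
trailing remainder of a chromosome joins its last window. The window
statistic is the **median** of the normalized counts (robust to
outlier sites). Each window takes the allowed state minimizing
Euclidean distance to the expected profile; ties break toward total
copy number 4, then toward lower |a − b| — this tie-break is what makes
a euploid-restricted model call an AAAAB chromosome AAAB, the
characteristic artifact of fixed-ploidy callers, which the test suite
reproduces deliberately. The default allowed-state set is the five
euploid states plus the aneuploid states actually observed in this
system (AAAAA, AAAAB, AAAABB, AABBBB); it is configurable. Runs of
identical window calls merge into segments; runs shorter than
`min_run = 2` windows are absorbed into the flanking state with the
nearer profile and counted as flagged. No HMM is used: windowed
nearest-profile classification is the minimal model consistent with
the data being summarized, and segment boundaries are only resolved to
window resolution (±1 window in the recovery tests).

## Array model and marker filtering

Array signals are modeled as the A-signal fraction
`a / total + N(0, noise_sd)` clipped to [0, 1]; DNA-mixture controls
sit at fixed fractions 0.5 (1:1), 0.75 (3:1) and 0.25 (1:3), diploid
parents at 1 and 0. The default `noise_sd = 0.03` reflects the
dispersion of well-behaved biallelic array clusters, where class
centers 0.25 apart are separated by several standard deviations.

The caller assigns each sample the dosage `d ∈ {0..4}` nearest to the
observed ratio (`|ratio − d/4|`) and rejects samples farther than
`max_sd = 3` pooled within-class standard deviations from their class
center. This is a defined, deterministic stand-in for published
mixture-model scorers; externally scored call tables can be ingested
directly (`hetrack.io.read_call_matrix`) and pushed through the same
filter cascade, which is the path for reproducing published
marker-retention counts.

The cascade retains a marker iff (1) it is called in every sample,
(2) the modal call of 1:1 mixtures is 2, (3) the modal calls of 3:1
and 1:3 mixtures are 3 and 1, (4) at least 25% (inclusive) of
tetraploid plants call 2, and (5) the marker has a B-genome physical
anchor. Modal ties that include the required value pass — "modal
score" has no published tie rule, and inclusive ties avoid discarding
informative markers. Every criterion is marker-local, so the outcome
is order-independent (tested by permuting criteria). Diploid control
scores are then pinned to the tetraploid scale (A-parent 4, B-parent
0).

## Composition tracking

Integer dosages map to labels 4→AAAA … 0→BBBB; markers order by
B-genome position within chromosome sets. Sets follow numerical
correspondence except 07/08, which aggregate rearranged parts of A07
and A08 (annotated, since dosage on those sets mixes two A
chromosomes). Per-set unbalanced-state fractions divide state counts
by the number of markers on the set; whether to then average or sum
over individuals is genuinely ambiguous in the source material, so
both are exposed (`mode="mean"` default — a per-individual average is
comparable across cohorts of different size). Transitions are scored
per marker along genotyped parent→child pairs; per-marker scoring is
the conservative, order-free choice, and segment-level summaries can
be layered on top. PCA runs on the centered, **unscaled** dosage
matrix (dosages share a scale, so variable scaling would only inflate
noise); missing calls are mean-imputed per marker.

Genetic groups of lineages are treated as pedigree-defined sets, not
re-derived by clustering: pedigree membership is the reproducible
part of such classifications.

## Phenotype model

Seed weight (g/seed) = baseline 0.13 + 0.015 × (B-copies − 2) summed
over designated loci + N(0, 0.01), floored just above zero. The
default locus sits at the distal end of chromosome set 06, where a
large-seed factor of B-genome origin is known to reside; the baseline
and effect size are chosen so that the spread between fixed BBBB and
fixed AAAA at the locus (±0.03 g) brackets the observed class means
(~0.107–0.160 g/seed) without any single segment explaining them
alone. Flower color follows the top of set 05: any A copy → yellow
(dominant); BBBB → orange, or white with silencing probability 0.5
(superdosage silencing; the true rate is not identifiable from the
handful of published BBBB plants, so a maximally uninformative default
is used). SPAD chlorophyll shifts with genome-wide B dosage (+4 units
per extra mean B copy) and pod metrics scale allometrically with seed
weight — these give the statistics module realistic correlated traits
but are not calibrated to instrument scales.

## The selection-response experiment

`response_experiment` contrasts a tetraploid population, whose
heritable variation is continuously generated by homoeologous
exchange, with fixed homozygous diploid controls that have none. Per
replicate: 14 founder lineages (about the number of first-year
lineages such an experiment maintains) run 13 unselected burn-in
generations (the material was roughly that old when selection began),
accumulating standing dosage variation; lineages are then ranked by
phenotype and split into heavy and light halves (mirroring how
lineages were assigned to selection classes once seed-size differences
became noticeable); three generations of divergent truncation
selection follow, choosing among 4 candidate seeds per plant the
heaviest or lightest phenotype; a final fresh phenotype per lineage
yields Δ = mean(heavy) − mean(light). Diploids undergo the same
procedure with phenotype = baseline + noise, so any diploid Δ is pure
sampling noise (|Δ| ≲ noise_sd·√(2/n) in expectation). Defaults:
`p_he = 0.1` (occasional multivalent pairing appropriate for a
segmental allotetraploid; the per-generation exchange rate is a free
parameter of the system, not a measured constant), `breakpoint_rate =
0.3` per set per generation, 20 replicates, two 5-Mb chromosome sets
(05 and 06) — dosage dynamics are segment-level, so physical scale
only affects breakpoint placement, and small sets keep the experiment
to seconds.

## Problem sizes and numerical choices

- Dosage-state recovery experiments: 8 chromosome sets × 1 Mb ×
  site rate 0.005 (~5000 diagnostic sites/set, 25 windows of 200
  sites), coverage 30×, one aneuploid or unbalanced target chromosome
  embedded among 7 balanced ones.
- Segregation checks: exact chain solve plus 10⁴ Monte-Carlo
  replicates (χ² goodness of fit, fixation probability within 4
  standard errors).
- Read-sampling oracles: coverage 1000 for law-of-large-numbers
  convergence, tolerance 1%.
- AB-site discovery keeps positions at exactly the 95% read-consensus
  threshold (the rule is "at least"), uses plain majority (>50%) for
  fragment consensus (only a depth rule, not a fraction rule, is
  defined for fragments), and considers substitutions only.
- Dosage calling rounds half-integer ratios to the even dosage
  (numpy's `rint`); midpoints are 0.125 from both centers and occur
  with probability zero under the noise model.

## Known limitations

- No mapping bias, GC/mappability correction, or error-rate model; the
  simulator cannot be used to study alignment artifacts, only
  inference behavior on clean counts.
- Homoeologous exchange is parameterized per segment and meiosis
  (`p_he`), not mechanistically (no pairing-partner model, no
  crossover interference).
- The nondisjunction model transmits whole-chromosome-set copy-number
  changes only; segmental duplications/deletions are out of scope.
- Phenotype models are additive with Gaussian noise; no dominance,
  epistasis or genotype-by-year interaction, so year pooling in
  `selection_delta` is exact in simulation while real data pool years
  to cancel environmental effects.
- The array caller is a nearest-class stand-in; it does not model the
  scale-selection behavior of mixture-model scorers when diploid
  controls are included.
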