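# hetrack

Tools for simulating and detecting **homoeologous-exchange-driven genome
composition change** in a young allotetraploid, and for quantifying its
consequences under artificial selection.

A neoallotetraploid formed from two diverged diploid parents carries two
copies of each parental subgenome (AABB). Because its chromosomes mostly
pair with homologs but occasionally with homoeologs (a *segmental*
allotetraploid), recombination between subgenomes shifts local dosage
away from 2A:2B, producing segments in states such as AAAB, ABBB, AAAA
and BBBB — and, with nondisjunction, aneuploid states like AAAAB. These
dosage shifts are heritable and phenotypically consequential (seed
weight, flower color, chlorophyll), so they are raw material for
selection. `hetrack` is aimed at researchers who want to detect such
states from sequencing or SNP-array data, track them across selfed
generations, and explore their population dynamics in simulation.

## What's inside

- **`hetrack.segregation`** — the dosage chain at the heart of the
  package. A segment with `a` A-copies out of 4 transmits a gamete that
  is either a deterministic disomic draw (balanced segments, one copy
  per subgenome) or a uniform 2-subset of the 4 copies (tetrasomic,
  probability `p_he` per meiosis for balanced segments, always for
  unbalanced ones). Selfing convolves two gamete draws; mean dosage is
  a martingale, so a dosage-`d` segment ultimately fixes AAAA with
  probability `d/4`.
- **`hetrack.simulate`** — parental genomes with diagnostic AB sites,
  single-seed-descent lineages, Poisson/binomial read counts,
  array-style signal ratios with diploid and DNA-mixture controls, and
  dosage-linked phenotypes.
- **`hetrack.absites`** — selection of subgenome-diagnostic variant
  positions from parental fragment + read evidence (four conditions,
  95% read-consensus rule).
- **`hetrack.wgsdosage`** — normalized allele counts
  (`normalizedA = (sampleA / sample cov) / (normrefA / normref cov)`,
  expectation `copies/2` against a 1:1 reference), nearest-profile
  window classification over the euploid + aneuploid state alphabet,
  and segment merging.
- **`hetrack.arraydosage`** — nearest-class 0–4 dosage calling from
  signal ratios, the control-mixture marker filter cascade, and diploid
  rescaling (A-parent → 4, B-parent → 0).
- **`hetrack.composition`** — ordered composition matrices, per-set
  unbalanced-state fractions, generation-to-generation transition
  statistics, flower-color prediction, PCA.
- **`hetrack.selection`** — the heavy-minus-light Δ (g/seed) statistic,
  assumption-guided group tests (Shapiro–Wilk/Levene →
  ANOVA+Tukey or Kruskal–Wallis+Dunn), and a forward-simulation
  experiment contrasting tetraploid and diploid selection response.

## Worked example

Simulate a lineage, sequence it, and call its composition:

```bash
$ hetrack simulate --seed 1 --out-dir sim
wrote synthetic study to sim/ (seed 1)
$ hetrack discover-sites sim/pileups.tsv --out sites.tsv
9996 diagnostic sites -> sites.tsv
$ hetrack dosage sim/counts.tsv sim/normref.tsv --out-prefix wgs
L0.6: 2 segments
```

The `dosage` step writes `wgs.L0.6.segments.tsv`: contiguous blocks of
the genome labeled with their inferred dosage state (AABB, AAAB, ...)
plus the median normalized A/B counts supporting each call.

Contrast selection response between the tetraploid and a diploid with
no heritable variation:

```bash
$ hetrack response-sim --seed 1
delta_tetraploid = 0.0276 g/seed, delta_diploid = -0.0002 g/seed
```

Here Δ is the difference between mean seed weight of heavy-selected and
light-selected lineages after three generations of divergent selection:
the tetraploid responds (homoeologous exchange keeps generating
heritable dosage variation at the seed-weight locus) while the fixed
homozygous diploid does not.

In Python, the same machinery composes directly:

```python
import hetrack as h

parents = h.simulate_parents(n_chrom=2, chrom_len=1_000_000, site_rate=0.005, seed=1)
founder = h.CompositionMap.uniform(parents.chrom_lengths)
lineage = h.simulate_lineage(founder, n_generations=6, p_he=0.1,
                             breakpoint_rate=0.3, seed=2)
counts = h.simulate_read_counts(lineage.last.composition, parents.ab_sites,
                                mean_cov=30.0, seed=3)
normref = h.simulate_read_counts(founder, parents.ab_sites, 30.0, seed=4)
track = h.normalize_counts(counts, normref)
segments = h.merge_segments(h.classify_windows(track, window_n=200))
```

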