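"""Synthetic neoallotetraploid generator.

Statistical stand-in for the study system: a colchicine-doubled
interspecific hybrid (AABB) advanced by single-seed descent in which
homoeologous exchange and occasional multivalent pairing shift local
subgenome dosage away from 2A:2B.  The generator produces

* a pair of diverged parental subgenomes with diagnostic biallelic sites,
* selfing lineages whose chromosome segments segregate under the
  disomic/tetrasomic model of :mod:`hetrack.segregation`,
* binomially sampled read allele counts at diagnostic sites,
* array-style signal ratios for plants plus diploid and DNA-mixture
  controls, and
* dosage-linked phenotypes (seed weight, flower color, pod metrics,
  chlorophyll).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segregation import InvalidStateError, gamete_segment_dosage
from .states import state_label

__all__ = [
    "SegmentState",
    "CompositionMap",
    "ParentalPair",
    "Individual",
    "Lineage",
    "TraitModel",
    "MarkerSignalTable",
    "InvalidCompositionError",
    "simulate_parents",
    "simulate_lineage",
    "simulate_read_counts",
    "simulate_array_signals",
    "simulate_phenotypes",
    "simulate_pileups",
]

ROLES = ("duranensis", "ipaensis", "mix11", "mix31", "mix13", "tetraploid")

#: Fixed A-signal fraction of each control role on the array.
ROLE_A_FRACTION = {
    "duranensis": 1.0,
    "ipaensis": 0.0,
    "mix11": 0.5,
    "mix31": 0.75,
    "mix13": 0.25,
}


class InvalidCompositionError(ValueError):
    """A composition map does not tile its chromosome sets."""


@dataclass(frozen=True)
class SegmentState:
    """A chromosome-set segment with its subgenome copy numbers.

    Coordinates are 1-based inclusive.  ``a_copies + b_copies`` is 2 for
    diploid controls, 4 for euploid tetraploids, and 3..6 under
    aneuploidy.
    """

    chrom_set: str
    start: int
    end: int
    a_copies: int
    b_copies: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad segment bounds [{self.start}, {self.end}]")
        if self.a_copies < 0 or self.b_copies < 0:
            raise ValueError("negative copy numbers")
        if not 2 <= self.total_copies <= 6:
            raise ValueError(f"total copies {self.total_copies} outside 2..6")

    @property
    def total_copies(self) -> int:
        return self.a_copies + self.b_copies

    @property
    def label(self) -> str:
        return state_label(self.a_copies, self.b_copies)


@dataclass
class CompositionMap:
    """Per-individual tiling of chromosome sets into dosage segments."""

    segments: dict[str, list[SegmentState]]

    def validate(self, chrom_lengths: dict[str, int] | None = None) -> None:
        """Check that segments tile each chromosome set without gap/overlap."""
        for cs, segs in self.segments.items():
            if not segs:
                raise InvalidCompositionError(f"chromosome set {cs} has no segments")
            expect = 1
            for seg in segs:
                if seg.chrom_set != cs:
                    raise InvalidCompositionError(
                        f"segment {seg} filed under set {cs}"
                    )
                if seg.start != expect:
                    raise InvalidCompositionError(
                        f"set {cs}: gap or overlap at position {expect}"
                    )
                expect = seg.end + 1
            if chrom_lengths is not None and segs[-1].end != chrom_lengths[cs]:
                raise InvalidCompositionError(
                    f"set {cs}: tiling ends at {segs[-1].end}, "
                    f"expected {chrom_lengths[cs]}"
                )

    @classmethod
    def uniform(
        cls, chrom_lengths: dict[str, int], a_copies: int = 2, b_copies: int = 2
    ) -> "CompositionMap":
        """One segment per chromosome set, all in the same state."""
        return cls(
            {
                cs: [SegmentState(cs, 1, int(length), a_copies, b_copies)]
                for cs, length in chrom_lengths.items()
            }
        )

    def state_at(self, chrom_set: str, pos: int) -> SegmentState:
        if chrom_set not in self.segments:
            raise InvalidCompositionError(f"no such chromosome set: {chrom_set}")
        for seg in self.segments[chrom_set]:
            if seg.start <= pos <= seg.end:
                return seg
        raise InvalidCompositionError(f"position {chrom_set}:{pos} outside tiling")

    def chrom_lengths(self) -> dict[str, int]:
        return {cs: segs[-1].end for cs, segs in self.segments.items()}

    def to_frame(self) -> pd.DataFrame:
        """BED-like table: 0-based half-open start/end (the sole 0-based output)."""
        rows = [
            (s.chrom_set, s.start - 1, s.end, s.a_copies, s.b_copies)
            for segs in self.segments.values()
            for s in segs
        ]
        return pd.DataFrame(
            rows, columns=["chrom_set", "start", "end", "a_copies", "b_copies"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionMap":
        segments: dict[str, list[SegmentState]] = {}
        for row in df.itertuples(index=False):
            segments.setdefault(str(row.chrom_set), []).append(
                SegmentState(
                    str(row.chrom_set),
                    int(row.start) + 1,
                    int(row.end),
                    int(row.a_copies),
                    int(row.b_copies),
                )
            )
        for segs in segments.values():
            segs.sort(key=lambda s: s.start)
        cmap = cls(segments)
        cmap.validate()
        return cmap


@dataclass(frozen=True)
class ParentalPair:
    """Two diverged parental subgenomes reduced to their diagnostic sites.

    ``ab_sites`` has columns chrom_set, pos (1-based), a_allele, b_allele
    with ``a_allele != b_allele`` at every row.
    """

    chrom_lengths: dict[str, int]
    ab_sites: pd.DataFrame
    seed: int


@dataclass
class Individual:
    id: str
    parent_id: str | None
    generation: int
    selection_class: str | None
    composition: CompositionMap


@dataclass
class Lineage:
    """A single-seed-descent chain of selfed individuals."""

    individuals: list[Individual]
    rng_seed: int

    def by_generation(self, gen: int) -> Individual:
        for ind in self.individuals:
            if ind.generation == gen:
                return ind
        raise KeyError(f"no individual at generation {gen}")

    @property
    def last(self) -> Individual:
        return self.individuals[-1]

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "parent_id": [i.parent_id for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
                "selection_class": [i.selection_class for i in self.individuals],
            }
        )


@dataclass(frozen=True)
class TraitModel:
    """Dosage-to-phenotype map.

    Seed weight (g/seed) is a baseline plus an additive effect per
    B-subgenome copy above 2 at designated loci (the large-seed factor
    sits at the distal end of chromosome set 06), plus Gaussian noise.
    Flower color is controlled by the top of chromosome set 05: any A
    copy gives yellow (dominant); BBBB gives orange, or white with
    probability ``silencing_prob_bbbb`` (superdosage silencing).
    """

    seed_weight_baseline: float = 0.13
    per_extra_b_effect: float = 0.015
    loci: tuple[tuple[str, int], ...] = (("06", 4_800_000),)
    flower_locus: tuple[str, int] = ("05", 100_000)
    noise_sd: float = 0.01
    silencing_prob_bbbb: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.silencing_prob_bbbb <= 1.0:
            raise ValueError("silencing_prob_bbbb must be a probability")

    @classmethod
    def for_genome(cls, chrom_lengths: dict[str, int], **kwargs) -> "TraitModel":
        """Place the default loci inside an arbitrary simulated genome.

        The large-seed locus goes at the distal end of chromosome set 06
        and the flower-color locus at the top of set 05 (falling back to
        the last/first configured set if those are absent).
        """
        sets = sorted(chrom_lengths)
        seed_set = "06" if "06" in chrom_lengths else sets[-1]
        flower_set = "05" if "05" in chrom_lengths else sets[0]
        kwargs.setdefault(
            "loci", ((seed_set, max(1, int(chrom_lengths[seed_set] * 0.96))),)
        )
        kwargs.setdefault(
            "flower_locus",
            (flower_set, max(1, int(chrom_lengths[flower_set] * 0.02))),
        )
        return cls(**kwargs)

    def genetic_seed_weight(self, composition: CompositionMap) -> float:
        w = self.seed_weight_baseline
        for cs, pos in self.loci:
            seg = composition.state_at(cs, pos)
            w += self.per_extra_b_effect * (seg.b_copies - 2)
        return w


@dataclass
class MarkerSignalTable:
    """Array-style signal ratios: markers x samples in [0, 1].

    ``markers`` carries marker id, B-genome chromosome anchor and
    position; ``ratios`` is indexed by marker id with one column per
    sample; ``roles`` maps sample id to its control/plant role.
    """

    markers: pd.DataFrame
    ratios: pd.DataFrame
    roles: dict[str, str]
    seed: int | None = None


# ---------------------------------------------------------------------------
# operations


def simulate_parents(
    n_chrom: int, chrom_len: int, site_rate: float, seed: int
) -> ParentalPair:
    """Generate diagnostic AB sites for a pair of diverged subgenomes.

    Each chromosome set gets Binomial(chrom_len, site_rate) diagnostic
    positions, uniform without replacement, with distinct parental
    alleles drawn from ACGT.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    if not 0.0 <= site_rate <= 1.0:
        raise ValueError("site_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = np.array(list("ACGT"))
    chrom_lengths = {f"{i + 1:02d}": int(chrom_len) for i in range(n_chrom)}
    frames = []
    for cs in chrom_lengths:
        n_sites = rng.binomial(chrom_len, site_rate)
        pos = np.sort(rng.choice(chrom_len, size=n_sites, replace=False)) + 1
        a_idx = rng.integers(0, 4, size=n_sites)
        # shift by 1..3 to guarantee a different base
        b_idx = (a_idx + rng.integers(1, 4, size=n_sites)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom_set": cs,
                    "pos": pos.astype(np.int64),
                    "a_allele": bases[a_idx],
                    "b_allele": bases[b_idx],
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom_set", "pos", "a_allele", "b_allele"]
    )
    return ParentalPair(chrom_lengths=chrom_lengths, ab_sites=sites, seed=seed)


def _split_at(segs: list[SegmentState], pos: int) -> list[SegmentState]:
    """Introduce a breakpoint after `pos` (segments keep their state)."""
    out: list[SegmentState] = []
    for seg in segs:
        if seg.start <= pos < seg.end:
            out.append(replace(seg, end=pos))
            out.append(replace(seg, start=pos + 1))
        else:
            out.append(seg)
    return out


def _self_offspring_map(
    parent: CompositionMap,
    p_he: float,
    breakpoint_rate: float,
    nondisjunction_rate: float,
    rng: np.random.Generator,
) -> CompositionMap:
    """One selfing step: breakpoints, then per-segment gamete convolution."""
    child: dict[str, list[SegmentState]] = {}
    for cs, segs in parent.segments.items():
        chrom_len = segs[-1].end
        n_bp = rng.poisson(breakpoint_rate)
        for _ in range(n_bp):
            if chrom_len > 1:
                segs = _split_at(segs, int(rng.integers(1, chrom_len)))
        # whole-chromosome nondisjunction: one gamete transmits +-1 copy
        delta = 0
        if nondisjunction_rate > 0 and rng.random() < nondisjunction_rate:
            delta = int(rng.choice([-1, 1]))
        new_segs = []
        for seg in segs:
            total = seg.total_copies
            base = total // 2
            sizes = []
            for gamete, d in ((0, delta), (1, 0)):
                k = base
                if total % 2:
                    k += int(rng.integers(0, 2))
                sizes.append(max(0, min(total, k + d)))
            a_child = 0
            t_child = 0
            for k in sizes:
                if total == 4 and seg.a_copies == 2 and delta == 0 and k == 2:
                    mode = "tetrasomic" if rng.random() < p_he else "disomic"
                else:
                    mode = "tetrasomic"
                a_child += gamete_segment_dosage(
                    seg.a_copies, mode, rng, total=total, nsample=k
                )
                t_child += k
            new_segs.append(
                replace(seg, a_copies=a_child, b_copies=t_child - a_child)
            )
        child[cs] = new_segs
    return CompositionMap(child)


def simulate_lineage(
    founder: CompositionMap,
    n_generations: int,
    p_he: float,
    breakpoint_rate: float,
    seed: int,
    nondisjunction_rate: float = 0.0,
    founder_id: str = "L0",
    selection_class: str | None = None,
) -> Lineage:
    """Advance a selfing lineage by single-seed descent.

    Per generation and per segment: dosage 0 or 4 transmits unchanged
    (absorbing); dosage 1 or 3 segregates tetrasomically; dosage 2
    segregates tetrasomically with probability ``p_he`` per meiosis
    (multivalent / homoeologous pairing) and disomically otherwise.  New
    breakpoints arrive Poisson(``breakpoint_rate``) per chromosome set
    per generation at uniform positions, splitting segments before
    segregation.  Offspring dosage is the sum of two independent gamete
    draws.
    """
    if not 0.0 <= p_he <= 1.0:
        raise ValueError("p_he must be a probability")
    founder.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    individuals = [
        Individual(founder_id, None, 0, selection_class, founder)
    ]
    current = founder
    for gen in range(1, n_generations + 1):
        current = _self_offspring_map(
            current, p_he, breakpoint_rate, nondisjunction_rate, rng
        )
        individuals.append(
            Individual(
                f"{founder_id}.{gen}",
                individuals[-1].id,
                gen,
                selection_class,
                current,
            )
        )
    return Lineage(individuals=individuals, rng_seed=seed)


def simulate_read_counts(
    composition: CompositionMap,
    sites: pd.DataFrame,
    mean_cov: float,
    seed: int,
    sample_id: str = "S0",
) -> pd.DataFrame:
    """Sample sequencing allele counts at diagnostic sites.

    Site depth ~ Poisson(mean_cov * total_copies / 4); the A count is
    Binomial(depth, a_copies / total_copies).  Returns a table with
    columns sample, chrom_set, pos, a_count, b_count, missing (depth 0).
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    empty = pd.DataFrame(
        columns=["sample", "chrom_set", "pos", "a_count", "b_count", "missing"]
    )
    if sites.empty:
        return empty
    frames = []
    for cs, group in sites.groupby("chrom_set", sort=False):
        if cs not in composition.segments:
            raise InvalidCompositionError(f"sites on unknown chromosome set {cs}")
        segs = composition.segments[cs]
        ends = np.array([s.end for s in segs])
        pos = group["pos"].to_numpy()
        if pos.max() > ends[-1] or pos.min() < 1:
            raise InvalidCompositionError(
                f"site outside segments on set {cs}"
            )
        idx = np.searchsorted(ends, pos)
        a = np.array([s.a_copies for s in segs])[idx]
        tot = np.array([s.total_copies for s in segs])[idx]
        depth = rng.poisson(mean_cov * tot / 4.0)
        a_count = rng.binomial(depth, np.where(tot > 0, a / tot, 0.0))
        frames.append(
            pd.DataFrame(
                {
                    "sample": sample_id,
                    "chrom_set": cs,
                    "pos": pos,
                    "a_count": a_count,
                    "b_count": depth - a_count,
                    "missing": depth == 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_array_signals(
    samples: list[tuple[str, str, CompositionMap | None]],
    markers: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> MarkerSignalTable:
    """Array signal ratios (A-signal fraction) for plants and controls.

    ``samples`` is a list of (sample_id, role, composition); controls
    (diploids and DNA mixtures) take their fixed A fraction from the
    role, tetraploid plants take ``a_copies / total_copies`` at each
    marker.  Gaussian noise is added and the ratio clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    marker_tab = markers.copy().reset_index(drop=True)
    if "marker" not in marker_tab.columns:
        marker_tab.insert(
            0,
            "marker",
            [
                f"AX{i:06d}"
                for i in range(len(marker_tab))
            ],
        )
    roles: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    for sample_id, role, composition in samples:
        if role not in ROLES:
            raise ValueError(f"unknown sample role: {role!r}")
        roles[sample_id] = role
        if role == "tetraploid":
            if composition is None:
                raise ValueError(f"tetraploid sample {sample_id} needs a composition")
            frac = np.empty(len(marker_tab))
            for i, row in enumerate(marker_tab.itertuples(index=False)):
                seg = composition.state_at(str(row.chrom_set), int(row.pos))
                frac[i] = seg.a_copies / seg.total_copies
        else:
            frac = np.full(len(marker_tab), ROLE_A_FRACTION[role])
        noisy = frac + rng.normal(0.0, noise_sd, size=len(marker_tab))
        columns[sample_id] = np.clip(noisy, 0.0, 1.0)
    ratios = pd.DataFrame(columns, index=marker_tab["marker"])
    marker_meta = marker_tab.rename(
        columns={"chrom_set": "chrom_B", "pos": "pos_B"}
    )
    marker_meta["chrom_B"] = "B" + marker_meta["chrom_B"].astype(str)
    return MarkerSignalTable(
        markers=marker_meta.set_index("marker"),
        ratios=ratios,
        roles=roles,
        seed=seed,
    )


def simulate_phenotypes(
    lineage: Lineage,
    model: TraitModel,
    seed: int,
    population: str = "ipadur1",
) -> pd.DataFrame:
    """Phenotype each individual of a lineage from its composition.

    Seed weight follows :meth:`TraitModel.genetic_seed_weight` plus
    Gaussian noise; flower color follows the set-05 locus with dominant
    yellow and BBBB silencing; pod area/perimeter/circularity scale with
    seed weight; SPAD chlorophyll shifts with the genome-wide B-dosage
    balance (darker leaves with a shift toward the B parent).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for ind in lineage.individuals:
        g = model.genetic_seed_weight(ind.composition)
        weight = g + rng.normal(0.0, model.noise_sd)
        weight = max(weight, 1e-4)
        fl_cs, fl_pos = model.flower_locus
        seg = ind.composition.state_at(fl_cs, fl_pos)
        if seg.a_copies >= 1:
            color = "yellow"
        else:
            color = (
                "white" if rng.random() < model.silencing_prob_bbbb else "orange"
            )
        # genome-wide mean B dosage (bp-weighted), 2.0 when balanced
        tot_bp = 0.0
        b_bp = 0.0
        for segs in ind.composition.segments.values():
            for s in segs:
                span = s.end - s.start + 1
                tot_bp += span
                b_bp += span * s.b_copies
        mean_b = b_bp / tot_bp
        seed_count = int(rng.poisson(8))
        pod_area = 120.0 * weight + rng.normal(0.0, 1.0)
        rows.append(
            {
                "plant_id": ind.id,
                "population": population,
                "year": ind.generation,
                "generation": ind.generation,
                "selection_class": ind.selection_class,
                "seed_count": seed_count,
                "seed_weight_g": weight,
                "max_seed_weight_g": weight + abs(rng.normal(0.0, model.noise_sd)),
                "pod_area": pod_area,
                "pod_perimeter": 4.2 * np.sqrt(max(pod_area, 0.1)),
                "pod_circularity": float(
                    np.clip(0.75 + 0.5 * (weight - 0.13) + rng.normal(0, 0.02), 0, 1)
                ),
                "spad": 38.0 + 4.0 * (mean_b - 2.0) + rng.normal(0.0, 1.0),
                "flower_color": color,
            }
        )
    return pd.DataFrame(rows)


def simulate_pileups(
    parents: ParentalPair,
    frag_depth: int = 2,
    read_depth: int = 60,
    n_nondiagnostic: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-free parental pileup evidence for AB-site discovery.

    For every diagnostic site, both evidence sources of each subgenome
    (10 kb fragment consensus depth and whole-genome read support) carry
    only the subgenome's own allele.  Optionally adds positions where
    both subgenomes share one allele (rejected by the difference rule).
    Returns a long table (chrom_set, pos, source, allele, count) sorted
    by position.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = np.array(list("ACGT"))
    rows = []
    for row in parents.ab_sites.itertuples(index=False):
        for source, allele, depth in (
            ("fragA", row.a_allele, frag_depth),
            ("readsA", row.a_allele, read_depth),
            ("fragB", row.b_allele, frag_depth),
            ("readsB", row.b_allele, read_depth),
        ):
            rows.append((row.chrom_set, int(row.pos), source, allele, depth))
    taken = {
        (r.chrom_set, int(r.pos)) for r in parents.ab_sites.itertuples(index=False)
    }
    chroms = list(parents.chrom_lengths)
    added = 0
    while added < n_nondiagnostic and chroms:
        cs = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(1, parents.chrom_lengths[cs] + 1))
        if (cs, pos) in taken:
            continue
        taken.add((cs, pos))
        allele = str(bases[int(rng.integers(0, 4))])
        for source, depth in (
            ("fragA", frag_depth),
            ("readsA", read_depth),
            ("fragB", frag_depth),
            ("readsB", read_depth),
        ):
            rows.append((cs, pos, source, allele, depth))
        added += 1
    df = pd.DataFrame(
        rows, columns=["chrom_set", "pos", "source", "allele", "count"]
    )
    return df.sort_values(["chrom_set", "pos", "source"], kind="stable").reset_index(
        drop=True
    )
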