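"""Discovery of subgenome-diagnostic AB variant positions.

A position is diagnostic when the two parental subgenomes carry
different consensus alleles.  Evidence comes from four independent
sources per position: fragmented parental assemblies mapped to the
B-genome reference (``fragA``/``fragB``) and parental whole-genome
short reads (``readsA``/``readsB``).

A position is kept iff

1. fragment and read evidence agree on a consensus allele within each
   subgenome,
2. the read consensus accounts for at least ``min_frac`` (default 95%)
   of mapped reads in both subgenomes,
3. fragment depth is at least ``min_frag_depth`` (default 1) in both,
4. the A and B consensus alleles differ.

Fragment consensus is a plain majority (> 50% of fragment depth).
Only substitutions are considered; indels are out of scope.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PositionPileup", "consensus_allele", "select_ab_sites", "pileups_from_frame"]

SOURCES = ("fragA", "readsA", "fragB", "readsB")


@dataclass
class PositionPileup:
    """Per-position allele evidence from the four parental sources."""

    chrom_set: str
    pos: int
    sources: dict[str, dict[str, int]] = field(default_factory=dict)

    def counts(self, source: str) -> dict[str, int]:
        return self.sources.get(source, {})


def consensus_allele(counts: Mapping[str, int], min_frac: float) -> str | None:
    """Allele reaching a fraction >= ``min_frac`` of total depth, else None.

    ``min_frac`` must lie in (0.5, 1] so the consensus is unique.
    Zero depth yields None.
    """
    if not 0.5 < min_frac <= 1.0:
        raise ValueError(f"min_frac must be in (0.5, 1], got {min_frac}")
    total = sum(counts.values())
    if total == 0:
        return None
    allele, best = max(counts.items(), key=lambda kv: kv[1])
    if best / total >= min_frac:
        return allele
    return None


def _majority_allele(counts: Mapping[str, int]) -> str | None:
    """Plain-majority consensus (> half of total depth)."""
    total = sum(counts.values())
    if total == 0:
        return None
    allele, best = max(counts.items(), key=lambda kv: kv[1])
    if 2 * best > total:
        return allele
    return None


def select_ab_sites(
    pileups: list[PositionPileup],
    min_frac: float = 0.95,
    min_frag_depth: int = 1,
) -> pd.DataFrame:
    """Apply the four diagnostic-site conditions to sorted pileups.

    Returns an AB-site table (chrom_set, pos, a_allele, b_allele)
    preserving input order.  Raises ``ValueError`` if pileups are not
    sorted by (chrom_set, pos).
    """
    keys = [(p.chrom_set, p.pos) for p in pileups]
    if keys != sorted(keys):
        raise ValueError("pileups must be sorted by (chrom_set, pos)")
    rows = []
    for p in pileups:
        frag_a = _majority_allele(p.counts("fragA"))
        frag_b = _majority_allele(p.counts("fragB"))
        # condition 3: minimum fragment depth in both subgenomes
        if (
            sum(p.counts("fragA").values()) < min_frag_depth
            or sum(p.counts("fragB").values()) < min_frag_depth
        ):
            continue
        # condition 2: read consensus at min_frac in both subgenomes
        reads_a = consensus_allele(p.counts("readsA"), min_frac)
        reads_b = consensus_allele(p.counts("readsB"), min_frac)
        if reads_a is None or reads_b is None:
            continue
        # condition 1: fragment and read evidence agree within subgenome
        if frag_a != reads_a or frag_b != reads_b:
            continue
        # condition 4: subgenome consensus alleles differ
        if reads_a == reads_b:
            continue
        rows.append((p.chrom_set, p.pos, reads_a, reads_b))
    return pd.DataFrame(rows, columns=["chrom_set", "pos", "a_allele", "b_allele"])


def pileups_from_frame(df: pd.DataFrame) -> list[PositionPileup]:
    """Build pileups from a long table (chrom_set, pos, source, allele, count)."""
    out: dict[tuple[str, int], PositionPileup] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom_set), int(row.pos))
        if key not in out:
            out[key] = PositionPileup(chrom_set=key[0], pos=key[1])
        src = out[key].sources.setdefault(str(row.source), {})
        src[str(row.allele)] = src.get(str(row.allele), 0) + int(row.count)
    return [out[k] for k in sorted(out)]
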