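"""Genome-composition matrices, generation-to-generation transitions,
flower-color prediction and ordination.

Chromosomes of the B-genome assembly anchor the marker order.  Each B
chromosome maps to a homoeologous "chromosome set"; sets 07 and 08 are
special because a reciprocal translocation in the A-genome lineage
means B07 pairs with parts of A07 and A08, and B08 with different parts
of A07 and A08.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .arraydosage import DosageCallMatrix
from .states import DOSAGE_TO_LABEL, MISSING_LABEL

__all__ = [
    "map_chrom_set",
    "chrom_set_note",
    "CompositionMatrix",
    "build_matrix",
    "unbalanced_fraction",
    "transition_stats",
    "flower_color_predict",
    "pca_scores",
]

#: B chromosomes of the default assembly.
DEFAULT_ASSEMBLY = tuple(f"B{i:02d}" for i in range(1, 11))

#: Sets aggregating rearranged A-genome parts.
REARRANGED_SET_NOTES = {
    "07": "aggregates B07 with parts of A07 and A08",
    "08": "aggregates B08 with different parts of A07 and A08",
}


def map_chrom_set(chrom_b: str, assembly: tuple[str, ...] = DEFAULT_ASSEMBLY) -> str:
    """Map a B-genome chromosome name to its chromosome-set label."""
    if chrom_b not in assembly:
        raise ValueError(f"unknown B chromosome: {chrom_b!r}")
    return chrom_b.removeprefix("B")


def chrom_set_note(set_label: str) -> str | None:
    """Annotation for sets that aggregate rearranged A-genome parts."""
    return REARRANGED_SET_NOTES.get(set_label)


@dataclass
class CompositionMatrix:
    """Markers (ordered by B-genome position within set) x individuals.

    ``labels`` holds AAAA/AAAB/AABB/ABBB/BBBB or ``missing``;
    ``positions`` carries (chrom_set, pos_B) per marker in row order.
    """

    labels: pd.DataFrame
    positions: pd.DataFrame


def build_matrix(matrix: DosageCallMatrix, positions: pd.DataFrame) -> CompositionMatrix:
    """Turn integer dosage calls into the ordered composition matrix.

    ``positions`` needs columns (marker, chrom_B, pos_B); every marker
    in the call matrix must be anchored.  Rows are sorted by
    (chrom_set, pos_B) and dosages mapped 4->AAAA .. 0->BBBB.
    """
    pos = positions.set_index("marker") if "marker" in positions.columns else positions
    if pos.index.duplicated().any():
        raise ValueError("duplicate marker in positions")
    if matrix.calls.index.duplicated().any():
        raise ValueError("duplicate marker in call matrix")
    missing_anchor = matrix.calls.index.difference(pos.index)
    if len(missing_anchor):
        raise ValueError(f"unanchored markers: {list(missing_anchor)[:5]}")
    pos = pos.loc[matrix.calls.index].copy()
    pos["chrom_set"] = [map_chrom_set(c) for c in pos["chrom_B"]]
    order = pos.sort_values(["chrom_set", "pos_B"], kind="stable").index
    labels = matrix.calls.loc[order].apply(
        lambda col: col.map(lambda d: MISSING_LABEL if pd.isna(d) else DOSAGE_TO_LABEL[int(d)])
    )
    return CompositionMatrix(
        labels=labels,
        positions=pos.loc[order, ["chrom_set", "pos_B"]],
    )


def unbalanced_fraction(matrix: CompositionMatrix, mode: str = "mean") -> pd.DataFrame:
    """Per chromosome set, normalized count of each unbalanced state.

    Counts of cells in each non-AABB state on a set are divided by the
    number of markers on that set.  ``mode="mean"`` averages the
    per-individual fractions (default); ``mode="sum"`` sums them over
    individuals.  Returns sets x states (AAAA, AAAB, ABBB, BBBB).
    """
    if mode not in {"mean", "sum"}:
        raise ValueError("mode must be 'mean' or 'sum'")
    states = [s for s in DOSAGE_TO_LABEL.values() if s != "AABB"]
    sets = sorted(matrix.positions["chrom_set"].unique())
    out = pd.DataFrame(0.0, index=sets, columns=states)
    for cs in sets:
        rows = matrix.positions["chrom_set"] == cs
        block = matrix.labels.loc[rows.to_numpy()]
        n_markers = len(block)
        for state in states:
            per_ind = (block == state).sum(axis=0) / n_markers
            out.loc[cs, state] = per_ind.sum() if mode == "sum" else per_ind.mean()
    out.index.name = "chrom_set"
    return out


def transition_stats(
    matrix: CompositionMatrix, pedigree: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score per-marker state transitions along parent-child pairs.

    ``pedigree`` needs columns (id, parent_id, generation).  For every
    genotyped child whose parent is also genotyped, each marker emits a
    (from_state, to_state) record; children without a genotyped parent
    are skipped.  Returns (records, summary) where summary tabulates,
    per from_state, the number of transmissions and the stability rate
    (fraction with to == from).
    """
    genotyped = set(matrix.labels.columns)
    records = []
    for row in pedigree.itertuples(index=False):
        child, parent = str(row.id), row.parent_id
        if child not in genotyped or parent is None or pd.isna(parent):
            continue
        if str(parent) not in genotyped:
            continue
        frm = matrix.labels[str(parent)]
        to = matrix.labels[child]
        ok = (frm != MISSING_LABEL) & (to != MISSING_LABEL)
        sub = pd.DataFrame(
            {
                "child": child,
                "parent": str(parent),
                "generation": int(row.generation),
                "chrom_set": matrix.positions["chrom_set"].to_numpy(),
                "marker": matrix.labels.index,
                "from_state": frm.to_numpy(),
                "to_state": to.to_numpy(),
            }
        )[ok.to_numpy()]
        records.append(sub)
    if records:
        rec = pd.concat(records, ignore_index=True)
    else:
        rec = pd.DataFrame(
            columns=[
                "child",
                "parent",
                "generation",
                "chrom_set",
                "marker",
                "from_state",
                "to_state",
            ]
        )
    if len(rec):
        summary = (
            rec.assign(stable=rec["from_state"] == rec["to_state"])
            .groupby("from_state")
            .agg(n=("stable", "size"), stability_rate=("stable", "mean"))
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["from_state", "n", "stability_rate"])
    return rec, summary


def flower_color_predict(state: str, silencing_prob: float = 0.5) -> dict[str, float]:
    """Flower-color distribution given the dosage state at the set-05 locus.

    Any A copy gives yellow (the A-parent allele is dominant); BBBB
    gives white with probability ``silencing_prob`` (superdosage
    silencing) and orange otherwise.
    """
    if state not in DOSAGE_TO_LABEL.values():
        raise ValueError(f"not a dosage-state label: {state!r}")
    if not 0.0 <= silencing_prob <= 1.0:
        raise ValueError("silencing_prob must be a probability")
    if state.count("A") >= 1:
        return {"yellow": 1.0, "orange": 0.0, "white": 0.0}
    return {"yellow": 0.0, "orange": 1.0 - silencing_prob, "white": silencing_prob}


def pca_scores(
    matrix: DosageCallMatrix,
    include_diploids: bool = True,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the centered (unscaled) dosage matrix.

    Samples are observations, markers variables.  Returns (scores,
    percent_variance); percent variances are non-increasing and sum to
    at most 100.  Missing calls are imputed with the marker mean.
    """
    calls = matrix.calls
    if not include_diploids:
        keep = [
            s
            for s in calls.columns
            if matrix.roles.get(s) not in {"duranensis", "ipaensis"}
        ]
        calls = calls[keep]
    X = calls.T.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 markers")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    if np.allclose(X, X[0]):
        raise ValueError("constant dosage matrix; PCA is degenerate")
    n_comp = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)  # PCA centers, does not scale
    scores = pd.DataFrame(
        coords,
        index=calls.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return scores, pca.explained_variance_ratio_ * 100.0
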