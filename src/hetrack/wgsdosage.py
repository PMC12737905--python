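"""Sequencing-based subgenome dosage: normalization, window
classification, and segmentation.

Raw A/B allele counts at diagnostic sites are normalized against a
synthetic 1:1 A:B reference read set by a ratio of coverage ratios::

    normalizedA = (sampleAcount / sample mean coverage)
                  / (normrefAcount / normref mean coverage)

so a balanced AABB sample has expectation 1.0 on both subgenomes and in
general the expectation is copies/2.  Non-overlapping windows of
consecutive sites are assigned the dosage state whose expected profile
(a/2, b/2) is nearest (Euclidean) to the window's median normalized
counts; window runs are merged into segments.

Restricting the allowed states to euploid configurations reproduces the
characteristic failure of fixed-ploidy genotype callers: an aneuploid
AAAAB chromosome is then called AAAB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import EXTENDED_STATES, MISSING_LABEL, state_label

__all__ = [
    "normalize_counts",
    "expected_profile",
    "classify_windows",
    "merge_segments",
]


def normalize_counts(
    sample: pd.DataFrame,
    normref: pd.DataFrame,
    sample_mean_coverage: float | None = None,
    normref_mean_coverage: float | None = None,
) -> pd.DataFrame:
    """Normalize per-site A/B counts against the 1:1 reference track.

    Both inputs need columns (chrom_set, pos, a_count, b_count); tables
    are joined on (chrom_set, pos).  Mean coverages default to the mean
    site depth (a+b) over all diagnostic sites of the respective track.
    Sites where a reference allele count is zero are flagged missing,
    never divided.

    Returns a table with normalized_a, normalized_b and a ``missing``
    flag.
    """
    merged = sample.merge(
        normref,
        on=["chrom_set", "pos"],
        suffixes=("", "_ref"),
        how="inner",
    )
    if sample_mean_coverage is None:
        sample_mean_coverage = float(
            (merged["a_count"] + merged["b_count"]).mean()
        )
    if normref_mean_coverage is None:
        normref_mean_coverage = float(
            (merged["a_count_ref"] + merged["b_count_ref"]).mean()
        )
    if not sample_mean_coverage > 0 or not normref_mean_coverage > 0:
        raise ValueError("mean coverages must be positive")
    ref_a = merged["a_count_ref"].to_numpy(dtype=float)
    ref_b = merged["b_count_ref"].to_numpy(dtype=float)
    missing = (ref_a == 0) | (ref_b == 0)
    if "missing" in merged.columns:
        missing |= merged["missing"].to_numpy(dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_a = (merged["a_count"] / sample_mean_coverage) / (
            ref_a / normref_mean_coverage
        )
        norm_b = (merged["b_count"] / sample_mean_coverage) / (
            ref_b / normref_mean_coverage
        )
    out = merged[["chrom_set", "pos"]].copy()
    out["normalized_a"] = np.where(missing, np.nan, norm_a)
    out["normalized_b"] = np.where(missing, np.nan, norm_b)
    out["missing"] = missing
    return out


def expected_profile(state: tuple[int, int]) -> tuple[float, float]:
    """Expected (normalizedA, normalizedB) for a dosage state.

    Relative to the 1:1 AABB reference the expectation is copies/2, so
    AABB -> (1, 1) and AAAB -> (1.5, 0.5).
    """
    a, b = state
    if a < 0 or b < 0 or not 3 <= a + b <= 6:
        raise ValueError(f"state {state} has total copies outside 3..6")
    return a / 2.0, b / 2.0


def _rank_states(
    med_a: float, med_b: float, allowed_states: frozenset[tuple[int, int]]
) -> tuple[int, int]:
    """Nearest allowed state; ties prefer total 4, then lower |a-b|."""
    best = min(
        allowed_states,
        key=lambda s: (
            (med_a - s[0] / 2.0) ** 2 + (med_b - s[1] / 2.0) ** 2,
            s[0] + s[1] != 4,
            abs(s[0] - s[1]),
        ),
    )
    return best


def classify_windows(
    track: pd.DataFrame,
    window_n: int = 200,
    allowed_states: frozenset[tuple[int, int]] = EXTENDED_STATES,
) -> pd.DataFrame:
    """Assign a dosage state to windows of consecutive diagnostic sites.

    Windows are non-overlapping runs of ``window_n`` sites per
    chromosome set (the trailing remainder joins the last window).  A
    window whose sites are more than 50% missing is labeled
    ``missing``.  Returns one row per window: chrom_set, start, end,
    n_sites, median_a, median_b, state, a_copies, b_copies.
    """
    if window_n < 20:
        raise ValueError("window_n must be >= 20 for a stable median")
    rows = []
    for cs, group in track.groupby("chrom_set", sort=False):
        group = group.sort_values("pos", kind="stable")
        n = len(group)
        n_windows = max(1, n // window_n)
        bounds = [
            (i * window_n, (i + 1) * window_n if i < n_windows - 1 else n)
            for i in range(n_windows)
        ]
        for lo, hi in bounds:
            win = group.iloc[lo:hi]
            n_missing = int(win["missing"].sum())
            row = {
                "chrom_set": cs,
                "start": int(win["pos"].iloc[0]),
                "end": int(win["pos"].iloc[-1]),
                "n_sites": len(win),
                "median_a": float(win["normalized_a"].median()),
                "median_b": float(win["normalized_b"].median()),
            }
            if n_missing * 2 > len(win):
                row.update(state=MISSING_LABEL, a_copies=-1, b_copies=-1)
            else:
                a, b = _rank_states(
                    row["median_a"], row["median_b"], allowed_states
                )
                row.update(state=state_label(a, b), a_copies=a, b_copies=b)
            rows.append(row)
    return pd.DataFrame(rows)


def merge_segments(windows: pd.DataFrame, min_run: int = 2) -> pd.DataFrame:
    """Merge maximal runs of identically-called windows into segments.

    Runs shorter than ``min_run`` windows are absorbed into the flanking
    state whose expected profile is nearer to the run's median profile,
    and counted in ``flagged_windows``.  Returns one row per segment:
    chrom_set, start, end, state, mean_a, mean_b, n_sites, n_windows,
    flagged_windows.
    """
    segments = []
    for cs, group in windows.groupby("chrom_set", sort=False):
        group = group.sort_values("start", kind="stable").reset_index(drop=True)
        # build runs of identical state
        runs: list[dict] = []
        for row in group.itertuples(index=False):
            if runs and runs[-1]["state"] == row.state:
                runs[-1]["rows"].append(row)
            else:
                runs.append(
                    {
                        "state": row.state,
                        "a": row.a_copies,
                        "b": row.b_copies,
                        "rows": [row],
                        "flagged": 0,
                    }
                )
        # absorb short runs into the nearer flank
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, run in enumerate(runs):
                if len(run["rows"]) >= min_run:
                    continue
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i + 1 < len(runs) else None
                med_a = float(np.nanmedian([r.median_a for r in run["rows"]]))
                med_b = float(np.nanmedian([r.median_b for r in run["rows"]]))

                def _dist(neighbor):
                    if neighbor is None or neighbor["state"] == MISSING_LABEL:
                        return np.inf
                    a, b = neighbor["a"], neighbor["b"]
                    return (med_a - a / 2.0) ** 2 + (med_b - b / 2.0) ** 2

                target = left if _dist(left) <= _dist(right) else right
                if target is None:
                    continue
                target["rows"] = (
                    target["rows"] + run["rows"]
                    if target is left
                    else run["rows"] + target["rows"]
                )
                target["flagged"] += len(run["rows"]) + run["flagged"]
                runs.pop(i)
                # re-merge now-adjacent identical runs
                j = 1
                while j < len(runs):
                    if runs[j]["state"] == runs[j - 1]["state"]:
                        runs[j - 1]["rows"].extend(runs[j]["rows"])
                        runs[j - 1]["flagged"] += runs[j]["flagged"]
                        runs.pop(j)
                    else:
                        j += 1
                changed = True
                break
        for run in runs:
            rows = sorted(run["rows"], key=lambda r: r.start)
            segments.append(
                {
                    "chrom_set": cs,
                    "start": rows[0].start,
                    "end": rows[-1].end,
                    "state": run["state"],
                    "mean_a": float(np.nanmean([r.median_a for r in rows])),
                    "mean_b": float(np.nanmean([r.median_b for r in rows])),
                    "n_sites": int(sum(r.n_sites for r in rows)),
                    "n_windows": len(rows),
                    "flagged_windows": run["flagged"],
                }
            )
    return pd.DataFrame(segments)
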