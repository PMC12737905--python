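"""Tetraploid allele-dosage calling from array signal ratios and the
control-mixture marker filter cascade.

Dosage is the count of A-subgenome alleles on a 0-4 scale.  The caller
assigns each sample the dosage whose ideal signal fraction ``d/4`` is
nearest to the observed ratio, then rejects samples lying farther than
``max_sd`` pooled within-class standard deviations from their class
center.  Markers are then filtered, in order, on

1. complete calls across all samples,
2. modal call of the 1:1 DNA-mixture controls equal to 2,
3. modal calls of the 3:1 and 1:3 mixtures equal to 3 and 1,
4. at least 25% of tetraploid plants called 2 (balanced AABB),
5. presence of a physical anchor on the B-genome assembly.

Each criterion is marker-local, so the cascade outcome is independent
of the order in which criteria are applied.  Finally diploid control
scores are rescaled to the tetraploid scale (A-genome parent to 4,
B-genome parent to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MarkerSignalTable

__all__ = [
    "DosageCallMatrix",
    "call_dosage",
    "marker_filter_cascade",
    "rescale_diploid_controls",
]


@dataclass
class DosageCallMatrix:
    """Marker x sample integer dosages (0-4; NaN = missing)."""

    calls: pd.DataFrame
    roles: dict[str, str]
    markers: pd.DataFrame | None = None

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.calls.columns if self.roles.get(s) == role]


def call_dosage(signals: MarkerSignalTable, max_sd: float = 3.0) -> DosageCallMatrix:
    """Nearest-class dosage calls with dispersion-based rejection.

    Per marker each sample gets the dosage d in 0..4 minimizing
    ``|ratio - d/4|``; samples farther than ``max_sd`` times the pooled
    within-class standard deviation from their class center are set
    missing.  A marker where every sample collapses into one class is
    still called.
    """
    if signals.ratios.empty:
        raise ValueError("empty signal table")
    ratios = signals.ratios.to_numpy(dtype=float)
    if np.nanmin(ratios) < 0 or np.nanmax(ratios) > 1:
        raise ValueError("signal ratios must lie in [0, 1]")
    dosage = np.rint(ratios * 4.0)
    resid = ratios - dosage / 4.0
    # pooled within-class s.d. per marker (residuals about class centers)
    pooled_sd = np.sqrt(np.mean(resid**2, axis=1, keepdims=True))
    reject = (pooled_sd > 0) & (np.abs(resid) > max_sd * pooled_sd)
    calls = pd.DataFrame(
        np.where(reject, np.nan, dosage),
        index=signals.ratios.index,
        columns=signals.ratios.columns,
    )
    return DosageCallMatrix(calls=calls, roles=dict(signals.roles), markers=signals.markers)


def _modal_calls(values: pd.Series) -> set[float]:
    """Set of modal values (inclusive ties), ignoring missing."""
    counts = values.dropna().value_counts()
    if counts.empty:
        return set()
    top = counts.max()
    return set(counts[counts == top].index)


def marker_filter_cascade(
    matrix: DosageCallMatrix,
    min_balanced_frac: float = 0.25,
    require_anchor: bool = True,
) -> pd.DataFrame:
    """Apply the control-mixture filter cascade; return per-marker verdicts.

    The result has one boolean column per criterion (``complete``,
    ``mix11_modal2``, ``mix31_modal3``, ``mix13_modal1``,
    ``balanced_frac``, ``anchored``) and a ``retained`` column that is
    their conjunction.  Modal ties that include the required value pass.
    """
    calls = matrix.calls
    mix11 = matrix.samples_with_role("mix11")
    mix31 = matrix.samples_with_role("mix31")
    mix13 = matrix.samples_with_role("mix13")
    tetra = matrix.samples_with_role("tetraploid")
    if not (mix11 and mix31 and mix13 and tetra):
        raise ValueError(
            "filter cascade requires mix11, mix31, mix13 and tetraploid samples"
        )
    out = pd.DataFrame(index=calls.index)
    out["complete"] = calls.notna().all(axis=1)
    out["mix11_modal2"] = calls[mix11].apply(lambda r: 2 in _modal_calls(r), axis=1)
    out["mix31_modal3"] = calls[mix31].apply(lambda r: 3 in _modal_calls(r), axis=1)
    out["mix13_modal1"] = calls[mix13].apply(lambda r: 1 in _modal_calls(r), axis=1)
    out["balanced_frac"] = (calls[tetra] == 2).mean(axis=1) >= min_balanced_frac
    if not require_anchor:
        out["anchored"] = True
    elif matrix.markers is None:
        out["anchored"] = False
    else:
        anchored = matrix.markers.reindex(calls.index)
        out["anchored"] = anchored["chrom_B"].notna() & anchored["pos_B"].notna()
    out["retained"] = out.all(axis=1)
    return out


def rescale_diploid_controls(matrix: DosageCallMatrix) -> DosageCallMatrix:
    """Force diploid control scores onto the tetraploid scale.

    Every call of an A-genome diploid control (*duranensis* role)
    becomes 4 and every B-genome control (*ipaensis*) becomes 0; all
    other samples are unchanged.
    """
    calls = matrix.calls.copy()
    for s in matrix.samples_with_role("duranensis"):
        calls[s] = 4.0
    for s in matrix.samples_with_role("ipaensis"):
        calls[s] = 0.0
    return DosageCallMatrix(calls=calls, roles=dict(matrix.roles), markers=matrix.markers)
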