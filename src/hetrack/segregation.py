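"""Tetrasomic and disomic segregation of segmental allele dosage.

In a segmental allotetraploid the four copies of a chromosome segment
(``a_copies`` from subgenome A, the rest from subgenome B) are
transmitted through selfing in one of two ways:

* **disomic** -- homologs pair strictly within subgenomes, so a balanced
  AABB segment transmits exactly one A and one B per gamete and the
  dosage never changes;
* **tetrasomic** -- multivalent (homoeologous) pairing makes the gamete
  an unordered draw of 2 of the 4 copies, so dosage segregates like an
  autotetraploid locus.

Unbalanced dosages (1 or 3 A copies) cannot pair disomically and always
segregate tetrasomically.  The mean dosage under tetrasomic selfing is a
martingale, so from dosage ``d`` the chain is eventually absorbed at
AAAA with probability ``d/4``.
"""

from __future__ import annotations

import numpy as np
from numpy.random import Generator
from scipy.stats import hypergeom


class InvalidStateError(ValueError):
    """A segregation mode was requested for an incompatible dosage."""


def gamete_segment_dosage(
    a_copies: int, mode: str, rng: Generator, total: int = 4, nsample: int = 2
) -> int:
    """Draw the A-copy count contributed by one gamete for one segment.

    Parameters
    ----------
    a_copies
        A-subgenome copies carried by the parent segment (0..total).
    mode
        ``"disomic"`` or ``"tetrasomic"``.
    rng
        numpy random generator.
    total
        Total copies carried by the parent segment (4 for euploid).
    nsample
        Copies transmitted by the gamete (2 for a reduced gamete).

    Returns
    -------
    int
        Number of A copies in the gamete.
    """
    if not 0 <= a_copies <= total:
        raise InvalidStateError(f"a_copies={a_copies} outside 0..{total}")
    if mode == "disomic":
        if total != 4 or nsample != 2:
            raise InvalidStateError("disomic pairing is defined only for 4 copies")
        if a_copies % 2:
            raise InvalidStateError(
                f"disomic segregation undefined for odd dosage {a_copies}; "
                "unbalanced segments must use tetrasomic mode"
            )
        return a_copies // 2
    if mode == "tetrasomic":
        if nsample == 0:
            return 0
        if nsample > total:
            raise InvalidStateError(f"gamete size {nsample} exceeds {total} copies")
        # uniform draw of `nsample` homologs without replacement
        return int(rng.hypergeometric(a_copies, total - a_copies, nsample))
    raise ValueError(f"unknown segregation mode: {mode!r}")


def gamete_pmf(a_copies: int, total: int = 4, nsample: int = 2) -> np.ndarray:
    """Exact tetrasomic gamete law: P(gamete A-count = k), k = 0..nsample."""
    k = np.arange(nsample + 1)
    return hypergeom.pmf(k, total, a_copies, nsample)


def selfing_transition_matrix(p_he: float) -> np.ndarray:
    """Dosage transition matrix for one selfing generation of a segment.

    Rows and columns index the A-copy dosage 0..4.  Dosages 0 and 4 are
    absorbing; 1 and 3 segregate tetrasomically; dosage 2 forms a
    multivalent (tetrasomic gamete) independently in each meiosis with
    probability ``p_he`` and otherwise pairs disomically (gamete carries
    exactly one A).  Offspring dosage is the sum of two independent
    gamete draws.
    """
    if not 0.0 <= p_he <= 1.0:
        raise ValueError(f"p_he must be a probability, got {p_he}")
    T = np.zeros((5, 5))
    for d in range(5):
        g = gamete_pmf(d)
        if d == 2:
            disomic = np.array([0.0, 1.0, 0.0])
            g = (1.0 - p_he) * disomic + p_he * g
        T[d] = np.convolve(g, g)
    return T


def fixation_probability(start_dosage: int, p_he: float = 1.0) -> float:
    """Probability that a segment starting at ``start_dosage`` fixes AAAA.

    Solved exactly from the selfing chain by linear absorption analysis.
    With any ``p_he > 0`` the only absorbing dosages are 0 and 4, and by
    the martingale property the answer is ``start_dosage / 4``; with
    ``p_he = 0`` dosage 2 is also absorbing.
    """
    if not 0 <= start_dosage <= 4:
        raise ValueError("start_dosage must be in 0..4")
    T = selfing_transition_matrix(p_he)
    absorbing = [d for d in range(5) if T[d, d] == 1.0]
    if start_dosage in absorbing:
        return 1.0 if start_dosage == 4 else 0.0
    transient = [d for d in range(5) if d not in absorbing]
    Q = T[np.ix_(transient, transient)]
    R = T[np.ix_(transient, [4])]
    # (I - Q) h = R, h = P(absorb at 4 | start transient)
    h = np.linalg.solve(np.eye(len(transient)) - Q, R).ravel()
    return float(h[transient.index(start_dosage)])
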