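"""Dosage-state vocabulary shared across the package.

A *dosage state* is the local count of A-subgenome versus B-subgenome
chromosome copies, written as a string of letters, e.g. ``AAAB`` for
3 A copies and 1 B copy.  Euploid tetraploid states sum to 4 copies;
aneuploid states sum to 3, 5 or 6.
"""

from __future__ import annotations

#: Euploid tetraploid states, as (a_copies, b_copies).
EUPLOID_STATES: frozenset[tuple[int, int]] = frozenset(
    {(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)}
)

#: Euploid states plus the aneuploid configurations observed by
#: whole-genome sequencing (AAAAA, AAAAB, AAAABB, AABBBB).
EXTENDED_STATES: frozenset[tuple[int, int]] = EUPLOID_STATES | {
    (5, 0),
    (4, 1),
    (4, 2),
    (2, 4),
}

#: Tetraploid-scale integer dosage (count of A alleles) -> state label.
DOSAGE_TO_LABEL: dict[int, str] = {
    4: "AAAA",
    3: "AAAB",
    2: "AABB",
    1: "ABBB",
    0: "BBBB",
}

LABEL_TO_DOSAGE: dict[str, int] = {v: k for k, v in DOSAGE_TO_LABEL.items()}

MISSING_LABEL = "missing"


def state_label(a_copies: int, b_copies: int) -> str:
    """Return the string label for a (a_copies, b_copies) state."""
    if a_copies < 0 or b_copies < 0:
        raise ValueError(f"negative copy number: ({a_copies}, {b_copies})")
    return "A" * a_copies + "B" * b_copies


def parse_state_label(label: str) -> tuple[int, int]:
    """Parse an ``AAAB``-style label into (a_copies, b_copies)."""
    a = label.count("A")
    b = label.count("B")
    if a + b != len(label) or not label:
        raise ValueError(f"not a dosage-state label: {label!r}")
    return a, b
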