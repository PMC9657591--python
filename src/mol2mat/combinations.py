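"""Enumeration of the fingerprint-combination cases.

The five best-performing fingerprint families (CDK, ECFP4, EPFP4, Graph,
ECFC4, in that column order) give C(5,2)+C(5,3)+C(5,4)+C(5,5) = 26 fusion
cases, labelled A..Z in size-major order and, within a size, lexicographically
by column position.  The printed check-mark table is frozen here and asserted
against the algorithmic enumeration, so any drift fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from string import ascii_uppercase

import pandas as pd

__all__ = ["CombinationCase", "FIVE_BEST", "enumerate_cases", "case_by_label", "cases_frame"]

#: Column order of the five best fingerprint families.
FIVE_BEST = ("CDK", "ECFP4", "EPFP4", "Graph", "ECFC4")

#: Frozen check-mark pattern: member column indices per label, A..Z.
_CHECKMARK_PATTERN: tuple[tuple[int, ...], ...] = (
    (0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4),
    (0, 1, 2), (0, 1, 3), (0, 1, 4), (0, 2, 3), (0, 2, 4), (0, 3, 4),
    (1, 2, 3), (1, 2, 4), (1, 3, 4), (2, 3, 4),
    (0, 1, 2, 3), (0, 1, 2, 4), (0, 1, 3, 4), (0, 2, 3, 4), (1, 2, 3, 4),
    (0, 1, 2, 3, 4),
)


@dataclass(frozen=True)
class CombinationCase:
    """One fusion case: its letter label and fingerprint members."""

    label: str
    members: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.members)


def enumerate_cases(fingerprints=FIVE_BEST) -> list[CombinationCase]:
    """All subsets of size 2..5 of five fingerprint names, labelled A..Z.

    Order is size-major, then lexicographic by member position — verified
    against the frozen check-mark pattern.
    """
    names = tuple(fingerprints)
    if len(names) != 5 or len(set(names)) != 5:
        raise ValueError(f"exactly 5 distinct fingerprint names required, got {names}")
    generated = [
        idx
        for size in (2, 3, 4, 5)
        for idx in _combinations(range(5), size)
    ]
    if tuple(generated) != _CHECKMARK_PATTERN:  # pragma: no cover - structural guard
        raise AssertionError("combination enumeration drifted from the frozen table")
    return [
        CombinationCase(label=ascii_uppercase[i], members=tuple(names[j] for j in idx))
        for i, idx in enumerate(generated)
    ]


def case_by_label(label: str, fingerprints=FIVE_BEST) -> CombinationCase:
    """Look up one case by its letter label (A..Z)."""
    label = label.upper()
    for case in enumerate_cases(fingerprints):
        if case.label == label:
            return case
    raise KeyError(f"no combination case labelled {label!r}")


def cases_frame(fingerprints=FIVE_BEST) -> pd.DataFrame:
    """The 26 cases as a check-mark DataFrame (one column per fingerprint)."""
    cases = enumerate_cases(fingerprints)
    frame = pd.DataFrame(
        [
            {
                "label": c.label,
                "cardinality": c.cardinality,
                **{name: name in c.members for name in fingerprints},
            }
            for c in cases
        ]
    ).set_index("label")
    return frame
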