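"""Protein-class over-representation: contingency tables and the
chi-square test.

Given the set of enriched proteins and a curated class list (all human
TFs, spliceosome components, ...), the question is whether the class
fraction among the enriched proteins differs from the fraction in the
full universe of inferred proteins.  The comparison uses the plain
Pearson chi-square on a 2x2 in-class/not-in-class x in-set/not-in-set
table, without continuity correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table: (a, b) top row, (c, d) bottom row.

    Rows index set membership (hit / non-hit) and columns class
    membership (in class / not in class) in :func:`build_contingency`,
    but the statistic is symmetric in that labeling.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def column_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def grand_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def class_fraction(members: set, class_list: set) -> tuple[int, float]:
    """In-class count and percentage (one decimal) of a protein set."""
    if not members:
        raise ValueError("empty member set")
    count = len(set(members) & set(class_list))
    return count, round(100.0 * count / len(members), 1)


def build_contingency(universe: set, class_list: set, hit_set: set) -> ContingencyTable2x2:
    """Cross-tabulate hit-set membership against class membership.

    a = hits in class, b = hits outside class, c = non-hit class
    members, d = the remainder; the grand total is the universe size.
    ``hit_set`` must be contained in ``universe``; the class list is
    intersected with the universe.
    """
    universe, class_list, hit_set = set(universe), set(class_list), set(hit_set)
    if not hit_set <= universe:
        stray = sorted(hit_set - universe)[:5]
        raise ValueError(f"hit set not contained in universe, e.g. {stray}")
    in_class = universe & class_list
    a = len(hit_set & in_class)
    b = len(hit_set) - a
    c = len(in_class) - a
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def chi2_test(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Returns (statistic, df=1, p).  Raises if any expected count is zero
    (a degenerate margin).
    """
    arr = table.as_array()
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    expected = rows @ cols / arr.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count: degenerate table margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)
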