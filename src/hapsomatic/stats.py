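"""Cohort contingency statistics and copy-number event classification.

Two-sided Fisher's exact p-values follow the point-probability convention:
the sum of hypergeometric probabilities of all tables with the observed
margins whose point probability does not exceed the observed table's
(within a small relative tolerance for floating-point ties). Group
frequency tables report per-group event fractions with pairwise unadjusted
Fisher tests, percentages rounded half-up for display. Copy-number calls
use the gain >= 4 / loss <= 1 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence
import warnings

from scipy.stats import fisher_exact as _scipy_fisher


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns event present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"count {name} must be non-negative")

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def degenerate(self) -> bool:
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Degenerate margins (an empty row or column) make the test undefined;
    p = 1 is returned with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    if table.degenerate:
        warnings.warn("degenerate 2x2 margins; Fisher p undefined, returning 1",
                      stacklevel=2)
        return 1.0
    return float(_scipy_fisher(table.rows, alternative="two-sided").pvalue)


def classify_cnv(copy_number: int, gain_min: int = 4, loss_max: int = 1) -> str:
    """Classify a total copy number as gain (>= 4), loss (<= 1) or neutral."""
    if isinstance(copy_number, bool) or not isinstance(copy_number, int):
        raise TypeError(f"copy number must be an integer, got {copy_number!r}")
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    if copy_number >= gain_min:
        return "gain"
    if copy_number <= loss_max:
        return "loss"
    return "neutral"


def percent_display(fraction: float) -> int:
    """Integer percentage, rounded half-up (0.625 -> 63)."""
    # round the percentage to 9 decimals first so binary representation
    # noise (0.615*100 = 61.499999...) cannot push a .5 boundary down
    return int(Decimal(str(round(fraction * 100, 9))).quantize(
        0, rounding=ROUND_HALF_UP))


def group_frequency_table(
    group_counts: Mapping[str, tuple[int, int]],
) -> dict:
    """Per-group event fractions and pairwise two-sided Fisher tests.

    ``group_counts`` maps group name to ``(n_event, n_total)``. Empty
    groups report a null fraction and are skipped in pairwise tests. No
    multiple-comparison adjustment is applied.
    """
    groups: dict[str, dict] = {}
    for name, (n_event, n_total) in group_counts.items():
        if n_event > n_total:
            raise ValueError(f"group {name}: n_event {n_event} > n_total {n_total}")
        fraction = n_event / n_total if n_total else None
        groups[name] = {
            "n_event": n_event,
            "n_total": n_total,
            "fraction": fraction,
            "percent": percent_display(fraction) if fraction is not None else None,
        }
    pairwise: dict[str, float] = {}
    for g1, g2 in combinations(group_counts, 2):
        e1, t1 = group_counts[g1]
        e2, t2 = group_counts[g2]
        if t1 == 0 or t2 == 0:
            continue
        pairwise[f"{g1} vs {g2}"] = fisher_exact_two_sided(
            [[e1, t1 - e1], [e2, t2 - e2]]
        )
    return {"groups": groups, "pairwise_fisher_p": pairwise}
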