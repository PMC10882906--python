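"""Kano attribute classification.

Each respondent answers every item twice — a forward question ("if the
service IS provided…") and a reverse question ("if it is NOT provided…") —
on the 5-category scale Like(1) / Should be(2) / It doesn't matter(3) /
Bearable(4) / Dislike(5). The 5x5 evaluation table maps each (forward,
reverse) pair to one of six attributes:

=========  =================  ==============================================
code       name               meaning
=========  =================  ==============================================
A          attractive         delights when present, tolerated when absent
O          one-dimensional    satisfaction tracks presence roughly linearly
M          must-be            expected; absence dissatisfies
I          indifferent        little effect either way
R          reversing          presence dissatisfies (preference reversed)
Q          questionable       contradictory answer pair (data-quality flag)
=========  =================  ==============================================

An item's attribute is assigned by the Maximum-Frequency rule: the
attribute with the highest respondent count wins; ties fall back to a
configurable priority order and are always surfaced in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .instrument import Cohort

__all__ = [
    "KanoAttribute",
    "KanoEvaluationTable",
    "ItemFrequency",
    "DominantAttribute",
    "DEFAULT_TIE_PRIORITY",
    "classify_pair",
    "tabulate_item",
    "dominant_attribute",
    "classify_cohort",
]


class KanoAttribute(str, Enum):
    ATTRACTIVE = "A"
    ONE_DIMENSIONAL = "O"
    MUST_BE = "M"
    INDIFFERENT = "I"
    REVERSING = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # noqa: D105 - print as the single-letter code
        return self.value


A = KanoAttribute.ATTRACTIVE
O = KanoAttribute.ONE_DIMENSIONAL  # noqa: E741
M = KanoAttribute.MUST_BE
I = KanoAttribute.INDIFFERENT  # noqa: E741
R = KanoAttribute.REVERSING
Q = KanoAttribute.QUESTIONABLE

#: Tie-break order for the Maximum-Frequency rule: the most obligation-like
#: attribute is treated as binding when frequencies tie.
DEFAULT_TIE_PRIORITY: tuple[KanoAttribute, ...] = (M, O, A, I, R, Q)


def _default_cells() -> dict[tuple[int, int], KanoAttribute]:
    cells: dict[tuple[int, int], KanoAttribute] = {}
    # forward = Like: contradictory on (1,1), attractive across the middle,
    # one-dimensional when its absence is disliked.
    cells[(1, 1)] = Q
    for r in (2, 3, 4):
        cells[(1, r)] = A
    cells[(1, 5)] = O
    # forward = Should be / It doesn't matter / Bearable: reversed if the
    # absence is liked, must-be if it is disliked, indifferent otherwise.
    for f in (2, 3, 4):
        cells[(f, 1)] = R
        for r in (2, 3, 4):
            cells[(f, r)] = I
        cells[(f, 5)] = M
    # forward = Dislike: reversed preference, contradictory on (5,5).
    for r in (1, 2, 3, 4):
        cells[(5, r)] = R
    cells[(5, 5)] = Q
    return cells


@dataclass(frozen=True)
class KanoEvaluationTable:
    """The 25-cell (forward, reverse) -> attribute lookup."""

    cells: Mapping[tuple[int, int], KanoAttribute]

    def __post_init__(self) -> None:
        expected = {(f, r) for f in range(1, 6) for r in range(1, 6)}
        if set(self.cells) != expected:
            raise ValueError("evaluation table must define all 25 (forward, reverse) cells")

    @classmethod
    def default(cls) -> "KanoEvaluationTable":
        return cls(_default_cells())

    def __getitem__(self, pair: tuple[int, int]) -> KanoAttribute:
        return self.cells[pair]

    def cells_for(self, attribute: KanoAttribute) -> tuple[tuple[int, int], ...]:
        """All (forward, reverse) pairs mapping to ``attribute``, row-major."""
        return tuple(
            (f, r)
            for f in range(1, 6)
            for r in range(1, 6)
            if self.cells[(f, r)] is attribute
        )


DEFAULT_TABLE = KanoEvaluationTable.default()


def classify_pair(
    forward: int, reverse: int, table: KanoEvaluationTable = DEFAULT_TABLE
) -> KanoAttribute:
    """Classify one (forward, reverse) answer pair via the evaluation table."""
    if not (1 <= forward <= 5 and 1 <= reverse <= 5):
        raise ValueError(f"answer codes must be in 1..5, got {(forward, reverse)}")
    return table[(forward, reverse)]


@dataclass
class ItemFrequency:
    """Attribute counts for one item over a cohort.

    ``n_missing`` counts respondents whose forward/reverse pair is
    incomplete for this item (per-item exclusion; whole respondents are
    never dropped).
    """

    item_id: str
    counts: dict[KanoAttribute, int]
    n_classified: int
    n_missing: int

    def __post_init__(self) -> None:
        for attr in KanoAttribute:
            self.counts.setdefault(attr, 0)
        if sum(self.counts.values()) != self.n_classified:
            raise ValueError(f"{self.item_id}: counts do not sum to n_classified")

    def count(self, attribute: KanoAttribute) -> int:
        return self.counts[attribute]


@dataclass
class DominantAttribute:
    """Maximum-Frequency result for one item, with tie metadata."""

    item_id: str
    attribute: KanoAttribute
    tied_with: frozenset[KanoAttribute] = field(default_factory=frozenset)
    tie_rule_applied: bool = False

    def __post_init__(self) -> None:
        if bool(self.tied_with) != self.tie_rule_applied:
            raise ValueError("tied_with must be nonempty iff tie_rule_applied")


def tabulate_item(
    cohort: Cohort, item_id: str, table: KanoEvaluationTable = DEFAULT_TABLE
) -> ItemFrequency:
    """Attribute frequency table for one item over all respondents."""
    if item_id not in cohort.instrument.item_ids:
        raise KeyError(f"unknown item_id {item_id!r}")
    counts = {attr: 0 for attr in KanoAttribute}
    n_missing = 0
    for rec in cohort.records:
        pair = rec.kano.get(item_id)
        if pair is None:
            n_missing += 1
        else:
            counts[classify_pair(*pair, table)] += 1
    return ItemFrequency(item_id, counts, len(cohort) - n_missing, n_missing)


def dominant_attribute(
    freq: ItemFrequency,
    tie_priority: Sequence[KanoAttribute] = DEFAULT_TIE_PRIORITY,
) -> DominantAttribute:
    """Apply the Maximum-Frequency rule to one item's attribute counts.

    When two or more attributes share the maximum count, the first in
    ``tie_priority`` wins and the others are reported in ``tied_with``.
    """
    if freq.n_classified <= 0:
        raise ValueError(f"{freq.item_id}: no classified responses")
    top = max(freq.counts.values())
    winners = [attr for attr in KanoAttribute if freq.counts[attr] == top]
    if len(winners) == 1:
        return DominantAttribute(freq.item_id, winners[0])
    order = {attr: rank for rank, attr in enumerate(tie_priority)}
    winners.sort(key=lambda attr: order.get(attr, len(order)))
    return DominantAttribute(
        freq.item_id,
        winners[0],
        tied_with=frozenset(winners[1:]),
        tie_rule_applied=True,
    )


def classify_cohort(
    cohort: Cohort,
    table: KanoEvaluationTable = DEFAULT_TABLE,
    tie_priority: Sequence[KanoAttribute] = DEFAULT_TIE_PRIORITY,
) -> list[tuple[ItemFrequency, DominantAttribute | None]]:
    """Tabulate and classify every instrument item, in instrument order.

    Items with no classified responses are reported with ``None`` in place
    of the dominant attribute rather than being dropped.
    """
    cohort.require_records()
    if not cohort.has_kano():
        raise ValueError("cohort has no Kano answer pairs")
    results: list[tuple[ItemFrequency, DominantAttribute | None]] = []
    for item_id in cohort.instrument.item_ids:
        freq = tabulate_item(cohort, item_id, table)
        dom = dominant_attribute(freq, tie_priority) if freq.n_classified > 0 else None
        results.append((freq, dom))
    return results
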