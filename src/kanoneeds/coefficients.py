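"""Satisfaction/importance coefficients, quadrant analysis, strategy mapping.

The Better–Worse coefficients summarise an item's attribute counts:

    SI  = (A + O) / (A + M + O + I)     satisfaction coefficient
    DSI = (M + O) / (A + M + O + I)     dissatisfaction / importance coefficient

Reversing (R) and questionable (Q) answers are excluded from the
denominator. Both coefficients are kept as exact rationals
(:class:`fractions.Fraction`); rounding happens only at display time
(round-half-even, 2 decimal places by default).

The importance–satisfaction matrix (IPA) places each item in a quadrant
with SI on the horizontal axis and DSI on the vertical axis, split at
configurable thresholds (default 0.5/0.5, boundary counting as "high"):

    I   Predominance         high SI, high DSI
    II  Improving            low SI,  high DSI
    III Secondary Improving  low SI,  low DSI
    IV  Reserving            high SI, low DSI

The Blue-Sea strategy turns the dominant attribute into an action:
consolidate must-be and one-dimensional items, optimize attractive items,
transform indifferent items; R/Q items are flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from .kano import DominantAttribute, ItemFrequency, KanoAttribute

__all__ = [
    "Quadrant",
    "ItemCoefficients",
    "QuadrantAssignment",
    "StrategyAction",
    "satisfaction_index",
    "dissatisfaction_index",
    "item_coefficients",
    "assign_quadrant",
    "blue_sea_action",
    "display_round",
    "ipa_summary",
    "plot_quadrants",
]

_A = KanoAttribute.ATTRACTIVE
_O = KanoAttribute.ONE_DIMENSIONAL
_M = KanoAttribute.MUST_BE
_I = KanoAttribute.INDIFFERENT


class Quadrant(str, Enum):
    PREDOMINANCE = "I"
    IMPROVING = "II"
    SECONDARY_IMPROVING = "III"
    RESERVING = "IV"

    @property
    def label(self) -> str:
        return {
            Quadrant.PREDOMINANCE: "Predominance Area I",
            Quadrant.IMPROVING: "Improving Area II",
            Quadrant.SECONDARY_IMPROVING: "Secondary Improving Area III",
            Quadrant.RESERVING: "Reserving Area IV",
        }[self]


@dataclass(frozen=True)
class ItemCoefficients:
    item_id: str
    si: Fraction
    dsi: Fraction
    denominator: int


@dataclass(frozen=True)
class QuadrantAssignment:
    item_id: str
    quadrant: Quadrant
    si_threshold: Fraction
    dsi_threshold: Fraction


@dataclass(frozen=True)
class StrategyAction:
    item_id: str
    action: str  # consolidate | optimize | transform | review
    rationale_code: str


def _denominator(freq: ItemFrequency) -> int:
    return sum(freq.count(a) for a in (_A, _M, _O, _I))


def satisfaction_index(freq: ItemFrequency) -> Fraction:
    """Exact SI = (A + O) / (A + M + O + I)."""
    den = _denominator(freq)
    if den == 0:
        raise ZeroDivisionError(
            f"{freq.item_id}: SI undefined, all classified answers are R/Q"
        )
    return Fraction(freq.count(_A) + freq.count(_O), den)


def dissatisfaction_index(freq: ItemFrequency) -> Fraction:
    """Exact DSI = (M + O) / (A + M + O + I)."""
    den = _denominator(freq)
    if den == 0:
        raise ZeroDivisionError(
            f"{freq.item_id}: DSI undefined, all classified answers are R/Q"
        )
    return Fraction(freq.count(_M) + freq.count(_O), den)


def item_coefficients(freq: ItemFrequency) -> ItemCoefficients:
    return ItemCoefficients(
        freq.item_id,
        si=satisfaction_index(freq),
        dsi=dissatisfaction_index(freq),
        denominator=_denominator(freq),
    )


def assign_quadrant(
    si: Fraction | float,
    dsi: Fraction | float,
    si_threshold: Fraction | float = Fraction(1, 2),
    dsi_threshold: Fraction | float = Fraction(1, 2),
    item_id: str = "",
) -> QuadrantAssignment:
    """Place a (SI, DSI) point in the importance–satisfaction matrix.

    A coordinate exactly at its threshold counts as "high".
    """
    si_threshold = Fraction(si_threshold)
    dsi_threshold = Fraction(dsi_threshold)
    for name, t in (("si_threshold", si_threshold), ("dsi_threshold", dsi_threshold)):
        if not 0 < t < 1:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {t}")
    if not (0 <= si <= 1 and 0 <= dsi <= 1):
        raise ValueError(f"SI/DSI must be in [0, 1], got ({si}, {dsi})")
    high_si = si >= si_threshold
    high_dsi = dsi >= dsi_threshold
    if high_si and high_dsi:
        quadrant = Quadrant.PREDOMINANCE
    elif high_dsi:
        quadrant = Quadrant.IMPROVING
    elif high_si:
        quadrant = Quadrant.RESERVING
    else:
        quadrant = Quadrant.SECONDARY_IMPROVING
    return QuadrantAssignment(item_id, quadrant, si_threshold, dsi_threshold)


_ACTIONS = {
    KanoAttribute.MUST_BE: ("consolidate", "must-be: absence dissatisfies"),
    KanoAttribute.ONE_DIMENSIONAL: ("consolidate", "one-dimensional: satisfaction tracks presence"),
    KanoAttribute.ATTRACTIVE: ("optimize", "attractive: presence delights"),
    KanoAttribute.INDIFFERENT: ("transform", "indifferent: little effect either way"),
    KanoAttribute.REVERSING: ("review", "data-quality/reversed preference"),
    KanoAttribute.QUESTIONABLE: ("review", "data-quality/reversed preference"),
}


def blue_sea_action(attribute: KanoAttribute, item_id: str = "") -> StrategyAction:
    """Map a dominant attribute to its Blue-Sea strategy action."""
    action, rationale = _ACTIONS[attribute]
    return StrategyAction(item_id, action, rationale)


def display_round(value: Fraction | float, decimals: int = 2) -> float:
    """Round-half-even display rounding, exact for rational inputs."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-decimals)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_EVEN))


def ipa_summary(
    items: Sequence[tuple[ItemFrequency, DominantAttribute | None]],
    si_threshold: Fraction | float = Fraction(1, 2),
    dsi_threshold: Fraction | float = Fraction(1, 2),
    display_decimals: int = 2,
) -> pd.DataFrame:
    """Full per-item coefficient/quadrant/action table.

    One row per item: attribute counts, dominant attribute with tie
    metadata, exact SI/DSI plus display-rounded columns, quadrant, and
    Blue-Sea action. Items whose denominator A+M+O+I is zero are listed
    with empty coefficient fields, never silently dropped.
    """
    if not items:
        raise ValueError("no items to summarize")
    rows = []
    for freq, dom in items:
        row: dict[str, object] = {"item_id": freq.item_id}
        for attr in KanoAttribute:
            row[attr.value] = freq.count(attr)
        row["n_classified"] = freq.n_classified
        row["n_missing"] = freq.n_missing
        row["attribute"] = dom.attribute.value if dom else ""
        row["tied_with"] = "|".join(sorted(a.value for a in dom.tied_with)) if dom else ""
        if dom is not None and _denominator(freq) > 0:
            coef = item_coefficients(freq)
            quad = assign_quadrant(
                coef.si, coef.dsi, si_threshold, dsi_threshold, freq.item_id
            )
            action = blue_sea_action(dom.attribute, freq.item_id)
            row.update(
                si=float(coef.si),
                dsi=float(coef.dsi),
                si_display=display_round(coef.si, display_decimals),
                dsi_display=display_round(coef.dsi, display_decimals),
                quadrant=quad.quadrant.value,
                action=action.action,
            )
        else:
            row.update(
                si=float("nan"),
                dsi=float("nan"),
                si_display=float("nan"),
                dsi_display=float("nan"),
                quadrant="",
                action="review" if dom is None else blue_sea_action(dom.attribute).action,
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["si_threshold"] = float(si_threshold)
    frame.attrs["dsi_threshold"] = float(dsi_threshold)
    return frame


def plot_quadrants(summary: pd.DataFrame, path: str | Path) -> Path:
    """Render the importance–satisfaction scatter with labelled quadrants."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = summary.attrs.get("si_threshold", 0.5)
    dt = summary.attrs.get("dsi_threshold", 0.5)
    fig, ax = plt.subplots(figsize=(6, 6))
    valid = summary.dropna(subset=["si", "dsi"])
    palette = {"A": "tab:orange", "O": "tab:blue", "M": "tab:red", "I": "tab:gray",
               "R": "tab:purple", "Q": "tab:brown"}
    for attr, group in valid.groupby("attribute"):
        ax.scatter(group["si"], group["dsi"], label=attr,
                   color=palette.get(attr, "k"), s=45, zorder=3)
    for _, row in valid.iterrows():
        ax.annotate(row["item_id"], (row["si"], row["dsi"]),
                    textcoords="offset points", xytext=(5, 4), fontsize=8)
    ax.axvline(st, color="k", lw=0.8)
    ax.axhline(dt, color="k", lw=0.8)
    for x, y, text in (
        (0.98, 0.98, "I Predominance"),
        (0.02, 0.98, "II Improving"),
        (0.02, 0.02, "III Secondary\nImproving"),
        (0.98, 0.02, "IV Reserving"),
    ):
        ax.text(x, y, text, transform=ax.transAxes, fontsize=8, color="0.4",
                ha="right" if x > 0.5 else "left", va="top" if y > 0.5 else "bottom")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Satisfaction coefficient (SI)")
    ax.set_ylabel("Importance coefficient (DSI)")
    ax.legend(title="attribute", fontsize=8, loc="center right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
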