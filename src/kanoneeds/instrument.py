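"""Instrument definition and respondent-data model.

A needs-assessment instrument here is a 12-item questionnaire administered
twice per respondent: once on a 4-level Likert agreement scale (the needs
scale proper) and once as Kano-style paired questions, where every item is
asked in a *forward* form ("if this service IS provided, how do you feel?")
and a *reverse* form ("if this service is NOT provided, how do you feel?"),
each answered on the 5-category scale Like / Should be / It doesn't matter /
Bearable / Dislike.

This module defines the instrument schema (:class:`InstrumentSpec`), the
per-respondent record, and the cohort container, plus readers/writers for
the wide CSV layout (one row per respondent, columns ``Q1..Q12`` for Likert
answers and ``Q1_f``/``Q1_r`` etc. for the Kano pairs) and the instrument
config file (YAML or JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

__all__ = [
    "InstrumentError",
    "Item",
    "InstrumentSpec",
    "RespondentRecord",
    "Cohort",
    "default_instrument",
    "load_instrument",
    "read_responses",
    "write_responses",
    "describe_demographics",
]

N_LIKERT_LEVELS = 4
N_KANO_LEVELS = 5

#: CSV column holding the respondent identifier.
ID_COLUMN = "respondent_id"


class InstrumentError(ValueError):
    """Raised when an instrument config or cohort violates the schema."""


class Item(NamedTuple):
    item_id: str
    label: str
    dimension_id: str


@dataclass(frozen=True)
class InstrumentSpec:
    """Questionnaire structure: dimensions, items, and answer categories.

    ``likert_levels`` maps positionally to integer scores 1..4 (index 0 is
    score 1); ``kano_levels`` maps positionally to codes 1..5 with the
    conventional order Like=1 .. Dislike=5.
    """

    name: str
    dimensions: tuple[tuple[str, str], ...]
    items: tuple[Item, ...]
    likert_levels: tuple[str, ...]
    kano_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.likert_levels) != N_LIKERT_LEVELS:
            raise InstrumentError(
                f"likert_levels: expected exactly {N_LIKERT_LEVELS} labels, "
                f"got {len(self.likert_levels)}"
            )
        if len(self.kano_levels) != N_KANO_LEVELS:
            raise InstrumentError(
                f"kano_levels: expected exactly {N_KANO_LEVELS} labels, "
                f"got {len(self.kano_levels)}"
            )
        dim_ids = [d for d, _ in self.dimensions]
        if len(set(dim_ids)) != len(dim_ids):
            raise InstrumentError("dimensions: duplicate dimension_id")
        seen: set[str] = set()
        for i, item in enumerate(self.items):
            if item.item_id in seen:
                raise InstrumentError(f"items[{i}].id: duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
            if item.dimension_id not in dim_ids:
                raise InstrumentError(
                    f"items[{i}].dimension: item {item.item_id!r} references "
                    f"unknown dimension {item.dimension_id!r}"
                )

    # -- convenience views -------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def dimension_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.dimensions)

    def dimension_label(self, dimension_id: str) -> str:
        return dict(self.dimensions)[dimension_id]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def dimension_items(self, dimension_id: str) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.dimension_id == dimension_id)

    @property
    def dimension_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.dimension_items(d)) for d in self.dimension_ids)

    def likert_code(self, value: object) -> int | None:
        """Map a raw CSV cell to a Likert score 1..4, or None if invalid."""
        return _to_code(value, N_LIKERT_LEVELS, self.likert_levels)

    def kano_code(self, value: object) -> int | None:
        """Map a raw CSV cell to a Kano answer code 1..5, or None if invalid."""
        return _to_code(value, N_KANO_LEVELS, self.kano_levels)


def _to_code(value: object, n_levels: int, labels: Sequence[str]) -> int | None:
    text = str(value).strip()
    if not text:
        return None
    try:
        code = int(float(text))
    except ValueError:
        lowered = text.lower()
        for i, label in enumerate(labels):
            if label.lower() == lowered:
                return i + 1
        return None
    if float(text) != code:
        return None
    return code if 1 <= code <= n_levels else None


@dataclass
class RespondentRecord:
    """One respondent: Likert answers, Kano (forward, reverse) pairs, demographics."""

    respondent_id: str
    likert: dict[str, int] = field(default_factory=dict)
    kano: dict[str, tuple[int, int]] = field(default_factory=dict)
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item_id, score in self.likert.items():
            if not 1 <= score <= N_LIKERT_LEVELS:
                raise InstrumentError(f"likert[{item_id}]: score {score} outside 1..4")
        for item_id, (f, r) in self.kano.items():
            if not (1 <= f <= N_KANO_LEVELS and 1 <= r <= N_KANO_LEVELS):
                raise InstrumentError(f"kano[{item_id}]: codes {(f, r)} outside 1..5")


@dataclass
class Cohort:
    """A set of respondent records under one instrument.

    ``validation`` counts valid / missing / out-of-range cells per column
    family as tallied by :func:`read_responses` (or left empty for cohorts
    built in memory). ``provenance`` records where the data came from (a
    file path, or a simulation seed line).
    """

    instrument: InstrumentSpec
    records: list[RespondentRecord]
    provenance: str = ""
    validation: dict[str, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def require_records(self) -> None:
        if not self.records:
            raise InstrumentError("cohort has no respondent records")

    def has_likert(self) -> bool:
        return any(r.likert for r in self.records)

    def has_kano(self) -> bool:
        return any(r.kano for r in self.records)

    def demographic_fields(self) -> tuple[str, ...]:
        fields: list[str] = []
        for rec in self.records:
            for key in rec.demographics:
                if key not in fields:
                    fields.append(key)
        return tuple(fields)


# ---------------------------------------------------------------------------
# Instrument config I/O


def default_instrument() -> InstrumentSpec:
    """The packaged 12-item / 5-dimension spiritual-care-needs instrument."""
    path = Path(__file__).parent / "data" / "nsts_instrument.yaml"
    return load_instrument(path)


def load_instrument(path: str | Path) -> InstrumentSpec:
    """Load and validate an instrument config (YAML or JSON).

    Raises :class:`InstrumentError` naming the offending field on any
    schema violation, and :class:`FileNotFoundError` for a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise InstrumentError(f"{path}: config root must be a mapping")
    for key in ("name", "dimensions", "items", "likert_levels", "kano_levels"):
        if key not in raw:
            raise InstrumentError(f"{path}: missing required key {key!r}")
    try:
        dimensions = tuple((str(d["id"]), str(d.get("label", d["id"]))) for d in raw["dimensions"])
        items = tuple(
            Item(str(it["id"]), str(it.get("label", it["id"])), str(it["dimension"]))
            for it in raw["items"]
        )
    except (KeyError, TypeError) as exc:
        raise InstrumentError(f"{path}: malformed dimension/item entry ({exc})") from exc
    return InstrumentSpec(
        name=str(raw["name"]),
        dimensions=dimensions,
        items=items,
        likert_levels=tuple(str(x) for x in raw["likert_levels"]),
        kano_levels=tuple(str(x) for x in raw["kano_levels"]),
    )


# ---------------------------------------------------------------------------
# Respondent CSV I/O


def _new_family_counter() -> dict[str, int]:
    return {"valid": 0, "missing": 0, "out_of_range": 0}


def read_responses(path: str | Path, spec: InstrumentSpec | None = None) -> Cohort:
    """Read a wide respondent CSV into a :class:`Cohort`.

    Expected columns: optional ``respondent_id``; ``<item_id>`` for Likert
    answers; ``<item_id>_f`` / ``<item_id>_r`` for Kano forward/reverse
    answers; anything else is treated as a demographic column. Blank or
    out-of-range cells become missing values and are tallied in the
    cohort's validation summary rather than aborting the read.
    """
    if spec is None:
        spec = default_instrument()
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        raise InstrumentError(f"{path}: no respondents")

    likert_cols = [c for c in frame.columns if c in spec.item_ids]
    kano_items = [
        i for i in spec.item_ids if f"{i}_f" in frame.columns and f"{i}_r" in frame.columns
    ]
    if not likert_cols and not kano_items:
        raise InstrumentError(f"{path}: no recognizable item columns for {spec.name!r}")
    known = (
        {ID_COLUMN}
        | set(likert_cols)
        | {f"{i}_f" for i in kano_items}
        | {f"{i}_r" for i in kano_items}
    )
    demo_cols = [c for c in frame.columns if c not in known]

    validation = {"likert": _new_family_counter(), "kano": _new_family_counter()}

    def classify_cell(raw: str, parse) -> tuple[int | None, str]:
        if not str(raw).strip():
            return None, "missing"
        code = parse(raw)
        return (code, "valid") if code is not None else (None, "out_of_range")

    records: list[RespondentRecord] = []
    seen_ids: set[str] = set()
    width = len(str(len(frame)))
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        rid = str(row_map.get(ID_COLUMN, "")).strip() or f"R{row_no:0{width}d}"
        if rid in seen_ids:
            raise InstrumentError(f"{path}: duplicate respondent_id {rid!r}")
        seen_ids.add(rid)

        likert: dict[str, int] = {}
        for col in likert_cols:
            code, status = classify_cell(row_map[col], spec.likert_code)
            validation["likert"][status] += 1
            if code is not None:
                likert[col] = code

        kano: dict[str, tuple[int, int]] = {}
        for item_id in kano_items:
            fwd, f_status = classify_cell(row_map[f"{item_id}_f"], spec.kano_code)
            rev, r_status = classify_cell(row_map[f"{item_id}_r"], spec.kano_code)
            validation["kano"][f_status] += 1
            validation["kano"][r_status] += 1
            if fwd is not None and rev is not None:
                kano[item_id] = (fwd, rev)

        demographics = {
            c: str(row_map[c]).strip() for c in demo_cols if str(row_map[c]).strip()
        }
        records.append(RespondentRecord(rid, likert, kano, demographics))

    return Cohort(
        instrument=spec,
        records=records,
        provenance=f"file:{path}",
        validation=validation,
    )


def write_responses(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV in the same dialect :func:`read_responses` expects.

    Round-trip safe: reading the written file reproduces every Likert value,
    Kano pair and demographic label; missing answers become blank cells.
    """
    cohort.require_records()
    spec = cohort.instrument
    columns: list[str] = [ID_COLUMN]
    for item_id in spec.item_ids:
        columns.append(item_id)
    for item_id in spec.item_ids:
        columns.extend([f"{item_id}_f", f"{item_id}_r"])
    columns.extend(cohort.demographic_fields())

    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {ID_COLUMN: rec.respondent_id}
        for item_id in spec.item_ids:
            if item_id in rec.likert:
                row[item_id] = rec.likert[item_id]
            if item_id in rec.kano:
                fwd, rev = rec.kano[item_id]
                row[f"{item_id}_f"] = fwd
                row[f"{item_id}_r"] = rev
        row.update(rec.demographics)
        rows.append(row)

    path = Path(path)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Demographics


def describe_demographics(cohort: Cohort) -> pd.DataFrame:
    """Count/percent table per demographic field, one row per category.

    Percentages are 100 * count / cohort size rounded to 1 decimal place;
    respondents without a value for a field appear under ``(missing)`` so
    counts always sum to the cohort size.
    """
    cohort.require_records()
    fields = cohort.demographic_fields()
    if not fields:
        raise InstrumentError("cohort has no demographic columns")
    n = len(cohort)
    rows = []
    for fld in fields:
        counts: dict[str, int] = {}
        for rec in cohort.records:
            category = rec.demographics.get(fld, "(missing)")
            counts[category] = counts.get(category, 0) + 1
        for category, count in counts.items():
            rows.append(
                {
                    "field": fld,
                    "category": category,
                    "count": count,
                    "percent": round(100.0 * count / n, 1),
                }
            )
    return pd.DataFrame(rows, columns=["field", "category", "count", "percent"])
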