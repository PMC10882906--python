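"""Synthetic-respondent generator and parameter-recovery experiments.

The generator draws, for every item, the (forward, reverse) answer pair
from a 25-cell multinomial over the evaluation table and the Likert answer
from an ordered-categorical distribution over scores 1..4, independently
per item. The Kano cell distribution is a one-parameter mixture: with a
*purity* p the probability mass p is spread uniformly over the cells of a
chosen *archetype* attribute and mass 1-p uniformly over all 25 cells, so
the family spans textbook-clean answers (p=1) to pure noise (p=0) while
keeping the generating attribute well defined.

Likert marginals can be pinned to a target item mean via a maximum-entropy
(exponential-family) fit, so simulated cohorts can emulate published
item-level means.

All randomness flows through one seeded ``numpy`` generator per cohort,
with a documented stream order (items outer, respondents inner, then
demographics), so identical configs yield identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .instrument import Cohort, InstrumentSpec, RespondentRecord, default_instrument
from .kano import (
    DEFAULT_TABLE,
    DEFAULT_TIE_PRIORITY,
    KanoAttribute,
    KanoEvaluationTable,
    dominant_attribute,
    ItemFrequency,
)

__all__ = [
    "ItemSimSpec",
    "SimConfig",
    "archetype_cell_matrix",
    "fit_likert_probs",
    "sample_item_pairs",
    "generate_cohort",
    "load_sim_config",
    "recovery_experiment",
    "cohort_from_counts",
]

_LIKERT_SCORES = np.arange(1, 5)
_PROB_TOL = 1e-9

#: Attribute order used when expanding count tables into answer pairs.
ATTRIBUTE_ORDER: tuple[KanoAttribute, ...] = (
    KanoAttribute.ATTRACTIVE,
    KanoAttribute.MUST_BE,
    KanoAttribute.ONE_DIMENSIONAL,
    KanoAttribute.INDIFFERENT,
    KanoAttribute.REVERSING,
    KanoAttribute.QUESTIONABLE,
)


def _cell_index(forward: int, reverse: int) -> int:
    """Row-major index of a (forward, reverse) cell in a flat 25-vector."""
    return (forward - 1) * 5 + (reverse - 1)


def archetype_cell_matrix(
    archetype: KanoAttribute,
    purity: float,
    table: KanoEvaluationTable = DEFAULT_TABLE,
) -> np.ndarray:
    """25-cell probability vector for an archetype at a given purity.

    Mass ``purity`` is spread uniformly over the cells classified as the
    archetype; mass ``1 - purity`` uniformly over all 25 cells.
    """
    if not 0 <= purity <= 1:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    cells = table.cells_for(archetype)
    if not cells:
        raise ValueError(f"archetype {archetype} has no cells in this table")
    probs = np.full(25, (1.0 - purity) / 25.0)
    for f, r in cells:
        probs[_cell_index(f, r)] += purity / len(cells)
    return probs


def fit_likert_probs(target_mean: float) -> np.ndarray:
    """Maximum-entropy probability vector over scores 1..4 with a given mean.

    Uses the exponential family p_k proportional to exp(theta*k); the mean is
    strictly increasing in theta, so the tilt solving mean = target is found
    by bracketing. Boundary targets collapse to point masses.
    """
    if not 1 <= target_mean <= 4:
        raise ValueError(f"target mean must be in [1, 4], got {target_mean}")
    if target_mean == 1:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if target_mean == 4:
        return np.array([0.0, 0.0, 0.0, 1.0])

    def tilted(theta: float) -> np.ndarray:
        w = np.exp(theta * (_LIKERT_SCORES - 2.5))
        return w / w.sum()

    theta = brentq(
        lambda t: float(tilted(t) @ _LIKERT_SCORES) - target_mean,
        -50.0,
        50.0,
        xtol=1e-13,
    )
    return tilted(theta)


@dataclass
class ItemSimSpec:
    """Simulation settings for one item.

    ``cell_probs``, when given, overrides (archetype, purity) as the answer
    -pair distribution; ``likert_probs`` defaults to uniform.
    """

    item_id: str
    archetype: KanoAttribute = KanoAttribute.INDIFFERENT
    purity: float = 0.8
    cell_probs: np.ndarray | None = None
    likert_probs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError(f"{self.item_id}: purity outside [0, 1]")
        self.likert_probs = np.asarray(self.likert_probs, dtype=float)
        if self.likert_probs.shape != (4,) or abs(self.likert_probs.sum() - 1) > _PROB_TOL:
            raise ValueError(f"{self.item_id}: likert_probs must be 4 values summing to 1")
        if self.cell_probs is not None:
            self.cell_probs = np.asarray(self.cell_probs, dtype=float)
            if self.cell_probs.shape != (25,) or abs(self.cell_probs.sum() - 1) > 1e-6:
                raise ValueError(f"{self.item_id}: cell_probs must be 25 values summing to 1")

    def resolved_cell_probs(self, table: KanoEvaluationTable = DEFAULT_TABLE) -> np.ndarray:
        if self.cell_probs is not None:
            return self.cell_probs / self.cell_probs.sum()
        return archetype_cell_matrix(self.archetype, self.purity, table)


@dataclass
class SimConfig:
    instrument: InstrumentSpec
    items: list[ItemSimSpec]
    n_respondents: int
    seed: int
    demographic_mixes: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        spec_ids = [s.item_id for s in self.items]
        if sorted(spec_ids) != sorted(self.instrument.item_ids):
            raise ValueError(
                "items must cover every instrument item exactly once; "
                f"got {spec_ids} vs {list(self.instrument.item_ids)}"
            )
        for fld, mix in self.demographic_mixes.items():
            if abs(sum(mix.values()) - 1) > 1e-6:
                raise ValueError(f"demographic mix {fld!r} does not sum to 1")

    def item_spec(self, item_id: str) -> ItemSimSpec:
        for s in self.items:
            if s.item_id == item_id:
                return s
        raise KeyError(item_id)


def sample_item_pairs(
    rng: np.random.Generator, cell_probs: np.ndarray, n: int
) -> list[tuple[int, int]]:
    """Draw n (forward, reverse) pairs from a 25-cell distribution."""
    idx = rng.choice(25, size=n, p=cell_probs)
    return [(int(i) // 5 + 1, int(i) % 5 + 1) for i in idx]


def generate_cohort(config: SimConfig, table: KanoEvaluationTable = DEFAULT_TABLE) -> Cohort:
    """Generate a cohort from a simulation config, deterministically per seed.

    Stream order is fixed: for each item in instrument order, first the n
    Kano pairs, then the n Likert scores; demographic fields are drawn
    last. Identical config and seed therefore give identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    spec = config.instrument

    kano_by_item: dict[str, list[tuple[int, int]]] = {}
    likert_by_item: dict[str, np.ndarray] = {}
    for item_id in spec.item_ids:
        item = config.item_spec(item_id)
        kano_by_item[item_id] = sample_item_pairs(rng, item.resolved_cell_probs(table), n)
        likert_by_item[item_id] = rng.choice(_LIKERT_SCORES, size=n, p=item.likert_probs)

    demo_by_field: dict[str, list[str]] = {}
    for fld, mix in config.demographic_mixes.items():
        categories = list(mix)
        probs = np.array([mix[c] for c in categories], dtype=float)
        draws = rng.choice(len(categories), size=n, p=probs / probs.sum())
        demo_by_field[fld] = [categories[int(i)] for i in draws]

    width = len(str(n))
    records = [
        RespondentRecord(
            respondent_id=f"S{i + 1:0{width}d}",
            likert={item_id: int(likert_by_item[item_id][i]) for item_id in spec.item_ids},
            kano={item_id: kano_by_item[item_id][i] for item_id in spec.item_ids},
            demographics={fld: values[i] for fld, values in demo_by_field.items()},
        )
        for i in range(n)
    ]
    return Cohort(
        instrument=spec,
        records=records,
        provenance=f"simulated:seed={config.seed},n={n}",
    )


def load_sim_config(
    path: str | Path, instrument: InstrumentSpec | None = None, seed: int | None = None
) -> SimConfig:
    """Read a simulation config (YAML); ``seed`` overrides the file's seed.

    Per-item entries take an ``archetype`` letter with optional ``purity``,
    or explicit ``cell_probs``; the Likert marginal comes from
    ``likert_mean`` (maximum-entropy fit) or explicit ``likert_probs``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if instrument is None:
        instrument = default_instrument()
    items = []
    for entry in raw["items"]:
        kwargs: dict[str, object] = {"item_id": str(entry["item"])}
        if "archetype" in entry:
            kwargs["archetype"] = KanoAttribute(entry["archetype"])
        if "purity" in entry:
            kwargs["purity"] = float(entry["purity"])
        if "cell_probs" in entry:
            kwargs["cell_probs"] = np.asarray(entry["cell_probs"], dtype=float)
        if "likert_probs" in entry:
            kwargs["likert_probs"] = np.asarray(entry["likert_probs"], dtype=float)
        elif "likert_mean" in entry:
            kwargs["likert_probs"] = fit_likert_probs(float(entry["likert_mean"]))
        items.append(ItemSimSpec(**kwargs))
    return SimConfig(
        instrument=instrument,
        items=items,
        n_respondents=int(raw["n_respondents"]),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        demographic_mixes={
            str(f): {str(c): float(p) for c, p in mix.items()}
            for f, mix in (raw.get("demographics") or {}).items()
        },
    )


def recovery_experiment(
    archetype: KanoAttribute,
    purity: float,
    n: int,
    replicates: int,
    seed: int,
    table: KanoEvaluationTable = DEFAULT_TABLE,
    tie_priority: Sequence[KanoAttribute] = DEFAULT_TIE_PRIORITY,
) -> float:
    """Fraction of replicates in which the Maximum-Frequency rule recovers
    the generating archetype.

    Each replicate draws n answer pairs from the archetype's cell
    distribution, tabulates attribute counts and applies the dominance
    rule with the given tie priority. Deterministic given the seed.
    """
    if replicates < 1 or n < 1:
        raise ValueError("n and replicates must be >= 1")
    probs = archetype_cell_matrix(archetype, purity, table)
    rng = np.random.default_rng(seed)
    cell_counts = rng.multinomial(n, probs, size=replicates)  # (replicates, 25)
    # 25 x 6 indicator: cell -> attribute, columns in tie-priority order so
    # argmax's first-max behaviour implements the tie rule.
    priority = list(tie_priority)
    indicator = np.zeros((25, len(priority)))
    for f in range(1, 6):
        for r in range(1, 6):
            indicator[_cell_index(f, r), priority.index(table[(f, r)])] = 1.0
    attr_counts = cell_counts @ indicator
    winners = attr_counts.argmax(axis=1)
    return float(np.mean(winners == priority.index(archetype)))


def cohort_from_counts(
    counts_by_item: Mapping[str, Mapping[KanoAttribute | str, int]],
    instrument: InstrumentSpec | None = None,
    table: KanoEvaluationTable = DEFAULT_TABLE,
) -> Cohort:
    """Deterministic cohort whose per-item attribute counts match a given table.

    For each attribute the first of its evaluation-table cells (row-major)
    is used as the representative answer pair, so tabulating the cohort
    reproduces the requested A/M/O/I/R/Q counts exactly. Items whose total
    falls short of the cohort size get missing pairs for the remainder.
    Intended for reproduction tests against published count tables.
    """
    if instrument is None:
        instrument = default_instrument()
    normalized: dict[str, dict[KanoAttribute, int]] = {}
    for item_id, counts in counts_by_item.items():
        if item_id not in instrument.item_ids:
            raise KeyError(f"unknown item_id {item_id!r}")
        normalized[item_id] = {KanoAttribute(k): int(v) for k, v in counts.items()}
    n = max(sum(c.values()) for c in normalized.values())

    pairs_by_item: dict[str, list[tuple[int, int] | None]] = {}
    for item_id in instrument.item_ids:
        pairs: list[tuple[int, int] | None] = []
        for attr in ATTRIBUTE_ORDER:
            cell = table.cells_for(attr)[0]
            pairs.extend([cell] * normalized.get(item_id, {}).get(attr, 0))
        pairs.extend([None] * (n - len(pairs)))
        pairs_by_item[item_id] = pairs

    width = len(str(n))
    records = []
    for i in range(n):
        kano = {
            item_id: pairs_by_item[item_id][i]
            for item_id in instrument.item_ids
            if pairs_by_item[item_id][i] is not None
        }
        records.append(RespondentRecord(f"C{i + 1:0{width}d}", kano=kano))
    return Cohort(instrument=instrument, records=records, provenance="counts-table")


def verify_counts(freq: ItemFrequency, expected: Mapping[KanoAttribute, int]) -> bool:
    """True if an item's tabulated counts equal an expected count map."""
    return all(freq.count(attr) == expected.get(attr, 0) for attr in KanoAttribute)
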