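"""Published aggregate data from the motivating study.

A cross-sectional survey of 357 Chinese inpatients with advanced breast
cancer (369 questionnaires delivered) answered the 12-item spiritual-care
-needs scale both on the 4-level Likert scale and as Kano forward/reverse
pairs. The study published, per item, the full A/M/O/I/R/Q attribute count
row together with the Likert item means and SDs; those aggregates are
shipped here so analyses and tests can reproduce the published coefficient
and quadrant surface, and so the synthetic generator can be pointed at
realistic marginals, without any raw respondent-level data (which was not
deposited).
"""

from __future__ import annotations

import pandas as pd

from .instrument import Cohort, InstrumentSpec, default_instrument
from .kano import KanoAttribute
from .simulate import ItemSimSpec, SimConfig, cohort_from_counts, fit_likert_probs

__all__ = [
    "N_RESPONDENTS",
    "N_DELIVERED",
    "STUDY_ATTRIBUTE_COUNTS",
    "STUDY_ITEM_MEANS",
    "STUDY_ITEM_SDS",
    "STUDY_DEMOGRAPHIC_MIXES",
    "study_counts_frame",
    "study_count_cohort",
    "study_sim_config",
]

#: Valid questionnaires analysed / questionnaires delivered.
N_RESPONDENTS = 357
N_DELIVERED = 369

#: Per-item Kano attribute counts (A, M, O, I, R, Q), n = 357 per item.
STUDY_ATTRIBUTE_COUNTS: dict[str, dict[str, int]] = {
    "Q1": {"A": 263, "M": 42, "O": 40, "I": 8, "R": 3, "Q": 1},
    "Q2": {"A": 34, "M": 184, "O": 123, "I": 14, "R": 1, "Q": 1},
    "Q3": {"A": 237, "M": 66, "O": 52, "I": 2, "R": 0, "Q": 0},
    "Q4": {"A": 71, "M": 113, "O": 165, "I": 6, "R": 1, "Q": 1},
    "Q5": {"A": 95, "M": 56, "O": 201, "I": 3, "R": 1, "Q": 1},
    "Q6": {"A": 73, "M": 41, "O": 48, "I": 193, "R": 2, "Q": 0},
    "Q7": {"A": 38, "M": 103, "O": 129, "I": 83, "R": 3, "Q": 1},
    "Q8": {"A": 54, "M": 115, "O": 149, "I": 36, "R": 2, "Q": 1},
    "Q9": {"A": 223, "M": 19, "O": 95, "I": 17, "R": 2, "Q": 1},
    "Q10": {"A": 61, "M": 218, "O": 71, "I": 6, "R": 1, "Q": 0},
    "Q11": {"A": 38, "M": 117, "O": 126, "I": 74, "R": 2, "Q": 0},
    "Q12": {"A": 71, "M": 53, "O": 15, "I": 217, "R": 1, "Q": 0},
}

#: Published per-item Likert means and SDs (scores 1..4).
STUDY_ITEM_MEANS: dict[str, float] = {
    "Q1": 2.89, "Q2": 2.81, "Q3": 2.58, "Q4": 2.45, "Q5": 2.70, "Q6": 2.47,
    "Q7": 2.52, "Q8": 2.63, "Q9": 3.04, "Q10": 3.27, "Q11": 2.08, "Q12": 1.72,
}
STUDY_ITEM_SDS: dict[str, float] = {
    "Q1": 0.71, "Q2": 0.69, "Q3": 0.77, "Q4": 0.71, "Q5": 0.69, "Q6": 0.66,
    "Q7": 0.70, "Q8": 0.72, "Q9": 0.71, "Q10": 0.75, "Q11": 0.65, "Q12": 0.73,
}

#: Headline demographic marginals of the cohort (used only to make
#: simulated report tables look realistic).
STUDY_DEMOGRAPHIC_MIXES: dict[str, dict[str, float]] = {
    "age": {"<60": 256 / 357, ">=60": 101 / 357},
    "religion": {"Yes": 45 / 357, "No": 312 / 357},
    "residence": {"Cities": 145 / 357, "Towns": 99 / 357, "Rural": 113 / 357},
}


def study_counts_frame() -> pd.DataFrame:
    """The published attribute-count table as a DataFrame (items in order)."""
    rows = [
        {"item_id": item_id, **counts}
        for item_id, counts in STUDY_ATTRIBUTE_COUNTS.items()
    ]
    return pd.DataFrame(rows)


def study_count_cohort(instrument: InstrumentSpec | None = None) -> Cohort:
    """Deterministic 357-respondent cohort reproducing the published counts.

    Answer pairs are reconstructed from the published per-item attribute
    counts via a fixed representative cell per attribute; the cohort is
    therefore exact on every attribute frequency, SI, DSI, dominant
    attribute and quadrant, though not on the unknowable within-attribute
    cell split.
    """
    return cohort_from_counts(STUDY_ATTRIBUTE_COUNTS, instrument=instrument)


def study_sim_config(
    n_respondents: int = N_RESPONDENTS,
    seed: int = 0,
    purity: float = 0.8,
    instrument: InstrumentSpec | None = None,
) -> SimConfig:
    """Simulation config emulating the study cohort.

    Each item's Kano archetype is the published dominant attribute (noise
    mixture at the given purity) and its Likert marginal is the maximum
    -entropy distribution matching the published item mean. Demographics
    follow the headline marginals.
    """
    if instrument is None:
        instrument = default_instrument()
    dominant = {
        item_id: max(counts, key=counts.get)
        for item_id, counts in STUDY_ATTRIBUTE_COUNTS.items()
    }
    items = [
        ItemSimSpec(
            item_id=item_id,
            archetype=KanoAttribute(dominant[item_id]),
            purity=purity,
            likert_probs=fit_likert_probs(STUDY_ITEM_MEANS[item_id]),
        )
        for item_id in instrument.item_ids
    ]
    return SimConfig(
        instrument=instrument,
        items=items,
        n_respondents=n_respondents,
        seed=seed,
        demographic_mixes=STUDY_DEMOGRAPHIC_MIXES,
    )
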