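"""Likert needs-scale scoring and summary statistics.

The 12-item needs scale is scored 1..4 per item (strongly disagree=1 ..
strongly agree=4), summed to a total in 12..48 and banded:

    mild      12-24
    moderate  25-36
    severe    37-48

Item and dimension summaries follow the usual questionnaire-report shape:
per-item mean and sample SD with a descending rank by mean, and per
dimension both the score sum (sum of its items per respondent) and the
item average, each with mean/SD over respondents, ranked by item average.
Cronbach's alpha and the rule-of-thumb minimum sample size round out the
scale utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import Cohort, RespondentRecord

__all__ = [
    "NeedsScore",
    "score_band",
    "score_respondent",
    "score_cohort",
    "item_summaries",
    "dimension_summaries",
    "cronbach_alpha",
    "minimum_sample_size",
    "questionnaire_recovery_rate",
]

MIN_TOTAL = 12
MAX_TOTAL = 48


@dataclass(frozen=True)
class NeedsScore:
    """Per-respondent needs-scale score; ``total`` is None when incomplete."""

    respondent_id: str
    total: int | None
    item_mean: float | None
    band: str | None
    reason: str = ""


def score_band(total: int) -> str:
    """Band a complete total: mild <=24, moderate 25-36, severe >=37."""
    if not MIN_TOTAL <= total <= MAX_TOTAL:
        raise ValueError(f"total {total} outside {MIN_TOTAL}..{MAX_TOTAL}")
    if total <= 24:
        return "mild"
    if total <= 36:
        return "moderate"
    return "severe"


def score_respondent(record: RespondentRecord, n_items: int = 12) -> NeedsScore:
    """Total, per-item mean and severity band for one respondent.

    The total requires all ``n_items`` answers; partial questionnaires get
    a missing score with the reason recorded rather than a biased sum.
    """
    if not record.likert:
        raise ValueError(f"{record.respondent_id}: no Likert data")
    if len(record.likert) < n_items:
        return NeedsScore(
            record.respondent_id,
            None,
            None,
            None,
            reason=f"only {len(record.likert)}/{n_items} items answered",
        )
    total = sum(record.likert.values())
    return NeedsScore(record.respondent_id, total, total / n_items, score_band(total))


def score_cohort(cohort: Cohort) -> pd.DataFrame:
    """Score every respondent; one row each, incomplete rows flagged."""
    cohort.require_records()
    if not cohort.has_likert():
        raise ValueError("no Likert data in cohort")
    n_items = len(cohort.instrument.item_ids)
    scores = [score_respondent(r, n_items) for r in cohort.records if r.likert]
    return pd.DataFrame(
        {
            "respondent_id": [s.respondent_id for s in scores],
            "total": [s.total for s in scores],
            "item_mean": [s.item_mean for s in scores],
            "band": [s.band for s in scores],
            "reason": [s.reason for s in scores],
        }
    )


def _likert_frame(cohort: Cohort) -> pd.DataFrame:
    """Respondent x item matrix of Likert scores (NaN where missing)."""
    cohort.require_records()
    if not cohort.has_likert():
        raise ValueError("no Likert data in cohort")
    items = cohort.instrument.item_ids
    data = {
        item: [float(r.likert[item]) if item in r.likert else np.nan for r in cohort.records]
        for item in items
    }
    return pd.DataFrame(data, index=[r.respondent_id for r in cohort.records])


def _rank_desc(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Dense ranks 1..n descending by value; ties broken by input order.

    Returns (rank, tied) where ``tied`` flags values shared with another
    entry.
    """
    order = sorted(range(len(values)), key=lambda i: (-values.iloc[i], i))
    ranks = pd.Series(0, index=values.index, dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks.iloc[i] = rank
    tied = values.duplicated(keep=False)
    return ranks, tied


def item_summaries(cohort: Cohort) -> pd.DataFrame:
    """Per-item mean, sample SD and descending rank by mean.

    Complete-case per item: each item's statistics use that item's
    available responses. Items with zero responses are kept with NaN
    statistics and flagged.
    """
    frame = _likert_frame(cohort)
    means = frame.mean()
    sds = frame.std(ddof=1)
    counts = frame.count()
    answered = means.dropna()
    ranks, tied = _rank_desc(answered)
    out = pd.DataFrame(
        {
            "item_id": frame.columns,
            "n": counts.values,
            "mean": means.values,
            "sd": sds.values,
        }
    )
    out["rank"] = [int(ranks[i]) if i in ranks.index else pd.NA for i in frame.columns]
    out["tied"] = [bool(tied[i]) if i in tied.index else False for i in frame.columns]
    out["flag"] = ["no responses" if c == 0 else "" for c in counts.values]
    return out


def dimension_summaries(cohort: Cohort) -> pd.DataFrame:
    """Per-dimension score sums and item averages with ranks.

    For each respondent with complete data on a dimension, the dimension
    score is the sum of its item scores and the dimension average is that
    sum divided by the item count; both are aggregated to mean/SD over
    respondents and dimensions are ranked descending by average mean.
    """
    frame = _likert_frame(cohort)
    spec = cohort.instrument
    rows = []
    for dim_id in spec.dimension_ids:
        cols = [it.item_id for it in spec.dimension_items(dim_id)]
        if not cols:
            raise ValueError(f"dimension {dim_id!r} has no items")
        block = frame[cols].dropna()
        sums = block.sum(axis=1)
        avgs = sums / len(cols)
        rows.append(
            {
                "dimension_id": dim_id,
                "label": spec.dimension_label(dim_id),
                "n_items": len(cols),
                "n": len(block),
                "score_sum_mean": sums.mean(),
                "score_sum_sd": sums.std(ddof=1),
                "item_avg_mean": avgs.mean(),
                "item_avg_sd": avgs.std(ddof=1),
            }
        )
    out = pd.DataFrame(rows)
    ranks, tied = _rank_desc(out["item_avg_mean"])
    out["rank"] = ranks.astype(int)
    out["tied"] = tied
    return out


def cronbach_alpha(cohort: Cohort, item_ids: list[str] | None = None) -> float:
    """Cronbach's alpha (internal consistency) over complete cases.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    with sample variances (n-1 denominator).
    """
    frame = _likert_frame(cohort)
    if item_ids is not None:
        frame = frame[list(item_ids)]
    k = frame.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    complete = frame.dropna()
    if len(complete) < 2:
        raise ValueError("Cronbach's alpha needs at least 2 complete respondents")
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = complete.var(ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)


def minimum_sample_size(
    n_questions: int, multiplier: int = 5, inflation: float = 0.10
) -> int:
    """Rule-of-thumb minimum sample size: ceil(items x multiplier x (1 + inflation)).

    The conventional 5-10 respondents per question, inflated (default 10%)
    for anticipated invalid questionnaires.
    """
    if n_questions <= 0 or multiplier <= 0 or inflation < 0:
        raise ValueError("n_questions and multiplier must be positive, inflation >= 0")
    return math.ceil(n_questions * multiplier * (1 + inflation))


def questionnaire_recovery_rate(n_valid: int, n_delivered: int) -> float:
    """Effective recovery rate as a percentage, 1 decimal place."""
    if n_delivered <= 0 or not 0 <= n_valid <= n_delivered:
        raise ValueError("need 0 <= n_valid <= n_delivered with n_delivered > 0")
    return round(100.0 * n_valid / n_delivered, 1)
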