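"""End-to-end analysis over one cohort, and the report bundle writer.

Runs whichever stages the data supports — the Kano attribute surface
(counts, SI/DSI, quadrants, Blue-Sea actions) when forward/reverse pairs
are present, and the Likert needs-scale summaries when Likert answers are
present — and writes the standard file bundle:

    items_kano.csv       per-item counts, attribute, SI/DSI, quadrant, action
    quadrant_plot.csv    plot coordinates + thresholds (optional PNG render)
    respondents_nsts.csv per-respondent total, item mean, severity band
    table3_like.csv      item and dimension means/SDs/ranks
    demographics.csv     count/percent table per demographic field
    report.md            human-readable summary
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import coefficients, kano, scoring
from .instrument import Cohort, describe_demographics
from .kano import DEFAULT_TABLE, DEFAULT_TIE_PRIORITY, KanoAttribute, KanoEvaluationTable

__all__ = ["AnalysisResult", "analyze_cohort", "write_bundle"]

#: Fraction of R+Q answers on an item above which a data-quality warning
#: is emitted (possible swapped forward/reverse answers).
RQ_WARN_FRACTION = 0.10


@dataclass
class AnalysisResult:
    cohort: Cohort
    items_kano: pd.DataFrame | None = None
    respondents_nsts: pd.DataFrame | None = None
    item_summary: pd.DataFrame | None = None
    dimension_summary: pd.DataFrame | None = None
    demographics: pd.DataFrame | None = None
    cronbach: float | None = None
    warnings: list[str] = field(default_factory=list)
    tie_events: int = 0

    def attribute_counts(self) -> dict[str, int]:
        """Number of items per dominant attribute."""
        if self.items_kano is None:
            return {}
        counts = self.items_kano["attribute"].value_counts().to_dict()
        return {a.value: int(counts.get(a.value, 0)) for a in KanoAttribute}

    def quadrant_counts(self) -> dict[str, int]:
        if self.items_kano is None:
            return {}
        counts = self.items_kano["quadrant"].value_counts().to_dict()
        return {q.value: int(counts.get(q.value, 0)) for q in coefficients.Quadrant}


def _log(message: str) -> None:
    print(f"kanoneeds: {message}", file=sys.stderr)


def analyze_cohort(
    cohort: Cohort,
    si_threshold: Fraction | float = Fraction(1, 2),
    dsi_threshold: Fraction | float = Fraction(1, 2),
    tie_priority: Sequence[KanoAttribute] = DEFAULT_TIE_PRIORITY,
    table: KanoEvaluationTable = DEFAULT_TABLE,
    display_decimals: int = 2,
) -> AnalysisResult:
    """Run every stage the cohort's data supports."""
    cohort.require_records()
    result = AnalysisResult(cohort=cohort)
    _log(f"read n={len(cohort)} respondents ({cohort.provenance})")
    for family, counter in cohort.validation.items():
        if counter.get("out_of_range") or counter.get("missing"):
            _log(
                f"{family} cells: {counter.get('valid', 0)} valid, "
                f"{counter.get('missing', 0)} missing, "
                f"{counter.get('out_of_range', 0)} out of range"
            )

    if cohort.has_kano():
        classified = kano.classify_cohort(cohort, table, tie_priority)
        summary = coefficients.ipa_summary(
            classified, si_threshold, dsi_threshold, display_decimals
        )
        spec = cohort.instrument
        summary.insert(1, "dimension", [spec.item(i).dimension_id for i in summary["item_id"]])
        summary.insert(2, "label", [spec.item(i).label for i in summary["item_id"]])
        result.items_kano = summary
        result.tie_events = sum(
            1 for _, dom in classified if dom is not None and dom.tie_rule_applied
        )
        if result.tie_events:
            _log(f"tie rule applied on {result.tie_events} item(s)")
        for freq, _ in classified:
            rq = freq.count(KanoAttribute.REVERSING) + freq.count(KanoAttribute.QUESTIONABLE)
            if freq.n_classified and rq / freq.n_classified > RQ_WARN_FRACTION:
                msg = (
                    f"{freq.item_id}: R+Q answers are {rq}/{freq.n_classified} "
                    f"(> {RQ_WARN_FRACTION:.0%}); check for swapped forward/reverse answers"
                )
                result.warnings.append(msg)
                _log("warning: " + msg)

    if cohort.has_likert():
        result.respondents_nsts = scoring.score_cohort(cohort)
        result.item_summary = scoring.item_summaries(cohort)
        result.dimension_summary = scoring.dimension_summaries(cohort)
        try:
            result.cronbach = scoring.cronbach_alpha(cohort)
        except ValueError as exc:
            result.warnings.append(f"Cronbach's alpha not computed: {exc}")

    if cohort.demographic_fields():
        result.demographics = describe_demographics(cohort)

    if result.items_kano is None and result.respondents_nsts is None:
        raise ValueError("cohort has neither Kano pairs nor Likert answers")
    return result


def _table3_like(result: AnalysisResult) -> pd.DataFrame:
    spec = result.cohort.instrument
    items = result.item_summary.set_index("item_id")
    dims = result.dimension_summary.set_index("dimension_id")
    rows = []
    for it in spec.items:
        d = dims.loc[it.dimension_id]
        i = items.loc[it.item_id]
        rows.append(
            {
                "dimension_id": it.dimension_id,
                "dimension_label": spec.dimension_label(it.dimension_id),
                "item_id": it.item_id,
                "item_label": it.label,
                "item_mean": i["mean"],
                "item_sd": i["sd"],
                "item_rank": i["rank"],
                "dim_n_items": d["n_items"],
                "dim_score_mean": d["score_sum_mean"],
                "dim_score_sd": d["score_sum_sd"],
                "dim_avg_mean": d["item_avg_mean"],
                "dim_avg_sd": d["item_avg_sd"],
                "dim_rank": d["rank"],
            }
        )
    return pd.DataFrame(rows)


def write_bundle(
    result: AnalysisResult, out_dir: str | Path, plot: bool = True
) -> list[Path]:
    """Write the analysis bundle; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if result.items_kano is not None:
        save(result.items_kano, "items_kano.csv")
        coords = result.items_kano[["item_id", "si", "dsi", "attribute", "quadrant"]].copy()
        coords = coords.rename(columns={"si": "x", "dsi": "y"})
        coords["si_threshold"] = result.items_kano.attrs.get("si_threshold", 0.5)
        coords["dsi_threshold"] = result.items_kano.attrs.get("dsi_threshold", 0.5)
        save(coords, "quadrant_plot.csv")
        if plot:
            written.append(coefficients.plot_quadrants(result.items_kano, out / "quadrant_plot.png"))
    if result.respondents_nsts is not None:
        save(result.respondents_nsts, "respondents_nsts.csv")
        save(_table3_like(result), "table3_like.csv")
    if result.demographics is not None:
        save(result.demographics, "demographics.csv")

    report = out / "report.md"
    report.write_text(render_report(result), encoding="utf-8")
    written.append(report)
    return written


def render_report(result: AnalysisResult) -> str:
    lines = ["# Needs-assessment report", ""]
    lines.append(f"Respondents analysed: {len(result.cohort)} ({result.cohort.provenance})")
    lines.append("")

    lines.append("## Kano attribute surface")
    if result.items_kano is None:
        lines.append("not available (no forward/reverse answer pairs)")
    else:
        attr_counts = result.attribute_counts()
        quad_counts = result.quadrant_counts()
        names = {
            "A": "attractive", "O": "one-dimensional", "M": "must-be",
            "I": "indifferent", "R": "reversing", "Q": "questionable",
        }
        for code in ("A", "O", "M", "I", "R", "Q"):
            if attr_counts.get(code):
                lines.append(f"- {attr_counts[code]} {names[code]} ({code}) item(s)")
        lines.append("")
        for quad in coefficients.Quadrant:
            members = result.items_kano.loc[
                result.items_kano["quadrant"] == quad.value, "item_id"
            ].tolist()
            if members:
                lines.append(f"- {quad.label}: {', '.join(members)}")
        lines.append("")
        lines.append("Blue-Sea actions:")
        for action in ("consolidate", "optimize", "transform", "review"):
            members = result.items_kano.loc[
                result.items_kano["action"] == action, "item_id"
            ].tolist()
            if members:
                lines.append(f"- {action}: {', '.join(members)}")
        lines.append(f"\nTie events: {result.tie_events}")
    lines.append("")

    lines.append("## Needs-scale scores")
    if result.respondents_nsts is None:
        lines.append("not available (no Likert data)")
    else:
        complete = result.respondents_nsts.dropna(subset=["total"])
        if len(complete):
            mean = complete["total"].mean()
            sd = complete["total"].std(ddof=1)
            lines.append(
                f"Total score {mean:.2f} +/- {sd:.2f} "
                f"(n={len(complete)} complete of {len(result.respondents_nsts)})"
            )
            bands = complete["band"].value_counts().to_dict()
            lines.append(
                "Severity bands: "
                + ", ".join(f"{b}={bands.get(b, 0)}" for b in ("mild", "moderate", "severe"))
            )
        if result.cronbach is not None:
            lines.append(f"Cronbach's alpha: {result.cronbach:.3f}")
        if result.dimension_summary is not None:
            top = result.dimension_summary.sort_values("rank").iloc[0]
            lines.append(
                f"Highest-need dimension: {top['label']} "
                f"(average {top['item_avg_mean']:.2f} +/- {top['item_avg_sd']:.2f})"
            )
    lines.append("")

    if result.warnings:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in result.warnings)
        lines.append("")
    return "\n".join(lines) + "\n"
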