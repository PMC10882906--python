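"""Reproduce the published Kano surface from the printed count rows.

The study printed every per-item A/M/O/I/R/Q count, so the whole
coefficient/attribute/quadrant surface is recomputable: this script runs
the full chain on a cohort reconstructed from those counts and writes the
item table, quadrant coordinates and scatter under results/published/.
"""

from pathlib import Path

from kanoneeds import analyze_cohort, datasets, write_bundle

OUT = Path(__file__).parents[1] / "results" / "published"


def main() -> None:
    cohort = datasets.study_count_cohort()
    result = analyze_cohort(cohort)
    write_bundle(result, OUT)
    summary = result.items_kano
    print(summary[["item_id", "attribute", "si_display", "dsi_display", "quadrant", "action"]]
          .to_string(index=False))
    print(f"\nitems per attribute: {result.attribute_counts()}")
    print(f"items per quadrant:  {result.quadrant_counts()}")
    print(f"bundle -> {OUT}")


if __name__ == "__main__":
    main()
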