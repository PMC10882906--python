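"""Generate the synthetic study cohort.

Draws 357 synthetic respondents whose per-item Kano archetypes and Likert
item means follow the published study marginals (purity 0.8 noise mixture),
and writes the wide respondent CSV the rest of the analysis consumes.
"""

from pathlib import Path

from kanoneeds import datasets, generate_cohort, write_responses

OUT = Path(__file__).parents[1] / "results"


def main() -> None:
    config = datasets.study_sim_config(n_respondents=357, seed=7)
    cohort = generate_cohort(config)
    path = write_responses(cohort, OUT / "cohort.csv")
    print(f"simulated {len(cohort)} respondents (seed {config.seed}) -> {path}")


if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    main()
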