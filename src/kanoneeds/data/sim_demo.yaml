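# Demo simulation config: a 357-respondent cohort whose per-item Kano
# archetypes and Likert item means follow the published study marginals.
n_respondents: 357
seed: 7
items:
  - {item: Q1, archetype: A, purity: 0.8, likert_mean: 2.89}
  - {item: Q2, archetype: M, purity: 0.8, likert_mean: 2.81}
  - {item: Q3, archetype: A, purity: 0.8, likert_mean: 2.58}
  - {item: Q4, archetype: O, purity: 0.8, likert_mean: 2.45}
  - {item: Q5, archetype: O, purity: 0.8, likert_mean: 2.70}
  - {item: Q6, archetype: I, purity: 0.8, likert_mean: 2.47}
  - {item: Q7, archetype: O, purity: 0.8, likert_mean: 2.52}
  - {item: Q8, archetype: O, purity: 0.8, likert_mean: 2.63}
  - {item: Q9, archetype: A, purity: 0.8, likert_mean: 3.04}
  - {item: Q10, archetype: M, purity: 0.8, likert_mean: 3.27}
  - {item: Q11, archetype: O, purity: 0.8, likert_mean: 2.08}
  - {item: Q12, archetype: I, purity: 0.8, likert_mean: 1.72}
demographics:
  age: {"<60": 0.717, ">=60": 0.283}
  religion: {"Yes": 0.126, "No": 0.874}
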