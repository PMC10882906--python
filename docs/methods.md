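# Methods

## Classification model

The evaluation table is the classical 5×5 Kano lookup: with forward and
reverse answers coded Like=1 … Dislike=5, row forward=1 is (Q, A, A, A, O),
rows forward∈{2,3,4} are (R, I, I, I, M), and row forward=5 is (R, R, R, R,
Q). A user-supplied 25-cell table can replace it; no other dialect (fuzzy or
analytical Kano) is supported. An item's attribute is the count maximizer
(Maximum-Frequency rule). Ties are resolved by a configurable priority,
default **M > O > A > I > R > Q** — when frequencies tie, the most
obligation-like attribute is treated as binding — and every tie is surfaced
in the output (`tied_with`, tie-event log lines), never silently absorbed.
R and Q stay in the frequency table and can win only on strict majority
under the default priority.

Missing handling is per item: a respondent with an incomplete (forward,
reverse) pair for an item is excluded from that item only, counted in
`n_missing`; respondents are never deleted listwise. Out-of-range CSV cells
are demoted to missing and tallied in a validation summary rather than
aborting the read, mirroring how survey quality control discards individual
unusable answers; an item whose R+Q share exceeds 10% triggers a
swapped-answers warning but no automatic repair.

## Coefficients and quadrants

SI = (A+O)/(A+M+O+I) and DSI = (M+O)/(A+M+O+I) are computed as exact
`fractions.Fraction` ratios; display rounding (round-half-even, 2 dp
default) is a formatting concern only. The published table this package
reproduces mixes 2-dp rounding and truncation in its last digit (e.g.
318/354 = 0.898 printed as 0.89), so reproduction tests compare at ±0.01
while internal arithmetic stays exact.

Quadrant thresholds are fixed at 0.5/0.5 by default, with a coordinate
exactly at threshold counting as "high". The source study never states its
cut lines; fixed 0.5/0.5 exactly reproduces every published placement,
whereas a mean-split does not (one item's SI of 203/354 ≈ 0.573 sits below
the item-mean SI ≈ 0.581 yet is placed in the high-SI Predominance area).
A mean-split option exists via explicit thresholds but is not the default.
The study's own prose contradicts its table and abstract on which
attributes sit in Areas II vs III; this package follows the count table and
the abstract (must-be in Improving II, indifferent in Secondary Improving
III), and the discrepancy is simply documented here.

Blue-Sea actions: M/O → consolidate, A → optimize, I → transform; R/Q map
to "review" with a data-quality rationale rather than forcing one of the
three strategy verbs, since the strategy is defined only for A/O/M/I.

## Needs-scale scoring

Items score 1–4; a total (12–48) requires all 12 answers — partial
questionnaires yield a missing total with the reason recorded. Bands: mild
≤ 24, moderate 25–36, severe ≥ 37. Item and dimension statistics are
complete-case per statistic; dispersion is the sample SD (n−1), the
conventional questionnaire-report choice. Rank ties are broken by
instrument order and flagged. Cronbach's α is the standard
k/(k−1)·(1 − Σs²ᵢ/s²_total) on complete cases. The minimum-sample-size
utility is the rule-of-thumb ceil(items × multiplier × (1 + inflation)),
default 5 per question with 10% inflation.

## Synthetic-respondent generator

Per item, (forward, reverse) pairs are drawn from a 25-cell multinomial:
mass *purity* spread uniformly over the cells of a chosen archetype
attribute, mass 1−purity uniformly over all 25 cells. This one-parameter
family spans textbook-clean (purity 1) to pure noise (purity 0) while
keeping the generating attribute well defined; nothing is known about the
real population's response noise, so a single interpretable dial was
preferred over a richer model. Likert answers are drawn independently per
item from a maximum-entropy (exponentially tilted) distribution on {1,2,3,4}
whose mean matches a target item mean (solved by bracketing to 1e-9;
boundary targets are point masses). One seeded `numpy` generator drives the
whole cohort with fixed stream order — items outer (Kano pairs then Likert
scores), demographics last — so identical config + seed gives byte-identical
CSVs.

The packaged study emulation uses the published marginals as its defaults:
n = 357 respondents, each item's archetype set to its published dominant
attribute at purity 0.8, Likert marginals fit to the published item means,
demographics following the headline mixes. A separate deterministic utility
reconstructs a cohort matching a published A/M/O/I/R/Q count row exactly
(fixed representative cell per attribute, first row-major table cell), used
for reproduction tests; the true within-attribute cell split is unknowable
from printed marginals.

What the generator does **not** emulate: inter-item correlation. Items are
independent, so a simulated cohort reproduces item means (hence the total's
mean ≈ 31.2 and its moderate band) but understates the total-score SD
(≈3.9 vs the reported 7.85) and cannot reproduce the reported internal
consistency (α 0.908) — independent items give α ≈ 0. Likewise no joint
model links need intensity to Kano answers, and demographics are a purely
categorical mixer. Passing tests therefore demonstrate correctness of the
pipeline arithmetic and classification behaviour under known generating
conditions, not distributional fidelity to the real cohort; raw-data-only
statistics are exercised, never asserted against the published values.

## Parameter recovery

`recovery_experiment` draws replicate multinomial count vectors at sample
size n, applies the dominance rule and reports the fraction recovering the
generating archetype, deterministic per seed; grids share one seed (common
random numbers) so recovery is monotone-comparable across purity. At purity
1 recovery is exact for every archetype even at n=10. At purity 0 the
argmax follows cell multiplicities (I holds 9/25 cells vs 7/25 for R), so
"recovery" of an indifferent archetype under pure noise is ≈0.97, not 1 —
the tests check this against an independent brute-force argmax oracle.

## Problem sizes and tolerances

Monte-Carlo checks in the suite use 100,000 draws for marginal-distribution
and Likert-mean checks at the low-level sampler, 5,000–10,000 respondents
for cohort-level checks, and 100–500 replicates for recovery experiments —
sizes at which the checked quantities' standard errors are an order of
magnitude below the asserted tolerances while the suite stays fast.
Probability vectors must sum to 1 within 1e-9 (1e-6 for user-supplied
25-cell tables); the Likert-fit mean is exact to 1e-9.
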