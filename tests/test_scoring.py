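"""Needs-scale scoring, severity bands, summaries, alpha and sample size."""

import statistics

import numpy as np
import pytest

from kanoneeds import (
    Cohort,
    RespondentRecord,
    cronbach_alpha,
    datasets,
    dimension_summaries,
    fit_likert_probs,
    item_summaries,
    minimum_sample_size,
    questionnaire_recovery_rate,
    score_band,
    score_cohort,
    score_respondent,
)


def _record(instrument, value):
    return RespondentRecord("r", likert={i: value for i in instrument.item_ids})


def _largest_remainder(probs, n):
    raw = probs * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts


def deterministic_likert_cohort(instrument, means, n=357):
    """Cohort whose empirical item means hit the targets to within ~3/n."""
    columns = {}
    for item_id, target in means.items():
        counts = _largest_remainder(fit_likert_probs(target), n)
        columns[item_id] = [s for s, c in zip(range(1, 5), counts) for _ in range(c)]
    records = [
        RespondentRecord(f"r{i}", likert={item: columns[item][i] for item in means})
        for i in range(n)
    ]
    return Cohort(instrument, records)


class TestScoreRespondent:
    @pytest.mark.parametrize(
        "value, total, band",
        [(1, 12, "mild"), (2, 24, "mild"), (3, 36, "moderate"), (4, 48, "severe")],
    )
    def test_constant_answers(self, instrument, value, total, band):
        score = score_respondent(_record(instrument, value))
        assert score.total == total and score.band == band
        assert score.item_mean == total / 12

    @pytest.mark.parametrize(
        "total, band",
        [(12, "mild"), (24, "mild"), (25, "moderate"), (31, "moderate"),
         (36, "moderate"), (37, "severe"), (48, "severe")],
    )
    def test_band_boundaries(self, total, band):
        assert score_band(total) == band

    @pytest.mark.parametrize("total", [11, 49])
    def test_band_rejects_impossible_totals(self, total):
        with pytest.raises(ValueError):
            score_band(total)

    def test_incomplete_respondent_gets_missing_total(self, instrument):
        rec = RespondentRecord("p", likert={"Q1": 3, "Q2": 2})
        score = score_respondent(rec)
        assert score.total is None and score.band is None
        assert "2/12" in score.reason

    def test_no_likert_data_rejected(self):
        with pytest.raises(ValueError, match="no Likert data"):
            score_respondent(RespondentRecord("p", kano={"Q1": (1, 5)}))


class TestSummaries:
    def test_constant_item_ranks_first(self, instrument):
        records = [
            RespondentRecord(
                f"r{i}", likert={i_id: (3 if i_id == "Q10" else 2) for i_id in instrument.item_ids}
            )
            for i in range(10)
        ]
        summary = item_summaries(Cohort(instrument, records))
        row = summary[summary["item_id"] == "Q10"].iloc[0]
        assert row["mean"] == 3.0 and row["rank"] == 1
        assert bool(row["tied"]) is False

    def test_published_item_mean_ranking_recovered(self, instrument):
        cohort = deterministic_likert_cohort(instrument, datasets.STUDY_ITEM_MEANS)
        summary = item_summaries(cohort).sort_values("rank")
        expected = ["Q10", "Q9", "Q1", "Q2", "Q5", "Q8", "Q3", "Q7", "Q6", "Q4", "Q11", "Q12"]
        assert summary["item_id"].tolist() == expected

    def test_tied_means_broken_by_instrument_order_and_flagged(self, instrument):
        records = [
            RespondentRecord(f"r{i}", likert={i_id: 2 for i_id in instrument.item_ids})
            for i in range(5)
        ]
        summary = item_summaries(Cohort(instrument, records))
        assert summary["tied"].all()
        assert summary.sort_values("rank")["item_id"].tolist() == list(instrument.item_ids)

    def test_ranks_are_a_permutation(self, sim_cohort):
        items = item_summaries(sim_cohort)
        assert sorted(items["rank"]) == list(range(1, 13))
        dims = dimension_summaries(sim_cohort)
        assert sorted(dims["rank"]) == list(range(1, 6))

    def test_dimension_aggregates_from_published_item_means(self, instrument):
        cohort = deterministic_likert_cohort(instrument, datasets.STUDY_ITEM_MEANS)
        dims = dimension_summaries(cohort).set_index("dimension_id")
        atmosphere = dims.loc["create_good_atmosphere"]
        assert atmosphere["item_avg_mean"] == pytest.approx(3.155, abs=0.02)
        thinking = dims.loc["help_thinking"]
        assert thinking["score_sum_mean"] == pytest.approx(7.62, abs=0.05)
        assert atmosphere["rank"] == 1

    def test_single_item_dimension_equals_item_mean(self, sim_cohort):
        items = item_summaries(sim_cohort).set_index("item_id")
        dims = dimension_summaries(sim_cohort).set_index("dimension_id")
        assert dims.loc["explore_spiritual_beliefs", "item_avg_mean"] == pytest.approx(
            items.loc["Q11", "mean"]
        )

    def test_dimension_avg_consistent_with_score_sum(self, sim_cohort):
        dims = dimension_summaries(sim_cohort)
        for _, row in dims.iterrows():
            assert row["item_avg_mean"] == pytest.approx(
                row["score_sum_mean"] / row["n_items"]
            )

    def test_aggregation_consistency_complete_case(self, sim_cohort):
        """Mean total = sum of item means = sum of dimension score means."""
        scores = score_cohort(sim_cohort).dropna(subset=["total"])
        items = item_summaries(sim_cohort)
        dims = dimension_summaries(sim_cohort)
        assert scores["total"].mean() == pytest.approx(items["mean"].sum())
        assert scores["total"].mean() == pytest.approx(dims["score_sum_mean"].sum())


class TestCronbachAlpha:
    def test_duplicated_items_give_alpha_one(self, instrument):
        rng = np.random.default_rng(5)
        values = rng.integers(1, 5, size=40)
        records = [
            RespondentRecord(f"r{i}", likert={"Q1": int(v), "Q2": int(v)})
            for i, v in enumerate(values)
        ]
        alpha = cronbach_alpha(Cohort(instrument, records), ["Q1", "Q2"])
        assert alpha == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self, instrument):
        rng = np.random.default_rng(2024)
        n = 10_000
        data = rng.integers(1, 5, size=(n, 12))
        records = [
            RespondentRecord(
                f"r{i}", likert=dict(zip(instrument.item_ids, map(int, row)))
            )
            for i, row in enumerate(data)
        ]
        assert abs(cronbach_alpha(Cohort(instrument, records))) < 0.05

    def test_matches_brute_force_on_toy_table(self, instrument):
        # 4 respondents x 3 items, alpha recomputed from first principles.
        table = {"Q1": [1, 2, 2, 4], "Q2": [2, 3, 2, 4], "Q3": [3, 4, 2, 3]}
        records = [
            RespondentRecord(f"r{i}", likert={q: table[q][i] for q in table})
            for i in range(4)
        ]
        k = 3
        totals = [sum(table[q][i] for q in table) for i in range(4)]
        expected = (k / (k - 1)) * (
            1 - sum(statistics.variance(table[q]) for q in table) / statistics.variance(totals)
        )
        alpha = cronbach_alpha(Cohort(instrument, records), list(table))
        assert alpha == pytest.approx(expected)

    def test_shift_leaves_alpha_and_shifts_means(self, instrument):
        rng = np.random.default_rng(8)
        base = rng.integers(1, 3, size=(200, 12))  # values in {1,2}: room to shift
        def cohort_of(data):
            return Cohort(
                instrument,
                [
                    RespondentRecord(
                        f"r{i}", likert=dict(zip(instrument.item_ids, map(int, row)))
                    )
                    for i, row in enumerate(data)
                ],
            )
        c0, c2 = cohort_of(base), cohort_of(base + 2)
        assert cronbach_alpha(c2) == pytest.approx(cronbach_alpha(c0))
        m0 = item_summaries(c0)["mean"]
        m2 = item_summaries(c2)["mean"]
        assert np.allclose(m2, m0 + 2)

    def test_degenerate_inputs_rejected(self, instrument):
        flat = Cohort(
            instrument,
            [RespondentRecord(f"r{i}", likert={"Q1": 2, "Q2": 2}) for i in range(5)],
        )
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(flat, ["Q1", "Q2"])
        one_item = Cohort(
            instrument, [RespondentRecord(f"r{i}", likert={"Q1": i % 4 + 1}) for i in range(5)]
        )
        with pytest.raises(ValueError, match="2 items"):
            cronbach_alpha(one_item, ["Q1"])


class TestSurveyUtilities:
    @pytest.mark.parametrize(
        "args, expected",
        [((24, 5, 0.10), 132), ((10, 10, 0.0), 100), ((12, 5, 0.10), 66)],
    )
    def test_minimum_sample_size(self, args, expected):
        assert minimum_sample_size(*args) == expected

    def test_minimum_sample_size_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            minimum_sample_size(0)

    def test_recovery_rate(self):
        assert questionnaire_recovery_rate(357, 369) == 96.7
        with pytest.raises(ValueError):
            questionnaire_recovery_rate(10, 0)
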