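"""Antisaccade trial classification, summaries and paired statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimconn.oculomotor import (
    UndefinedSummaryError,
    change_scores,
    classify_trial,
    classify_trials,
    latency_distribution,
    paired_t,
    paired_t_from_summary,
    summarize_subject,
    summarize_trials,
)
from conftest import make_trials


@pytest.mark.parametrize(
    "target, direction, latency, expected",
    [
        ("right", "right", 200.0, "error"),  # saccade toward the stimulus
        ("right", "left", 85.0, "anticipatory"),  # < 90 ms removed
        ("left", "right", 300.0, "correct"),
        ("left", "left", 90.0, "error"),  # boundary latency counts as valid
        ("left", "right", 89.999, "anticipatory"),
        ("right", "none", 200.0, "invalid"),  # no saccade detected
        ("right", "right", np.nan, "invalid"),
    ],
)
def test_trial_classification(target, direction, latency, expected):
    assert classify_trial(target, direction, latency) == expected


def test_vectorized_classification_matches_scalar():
    rng = np.random.default_rng(7)
    rows = []
    for _ in range(300):
        rows.append(
            (
                "s1",
                "on",
                rng.choice(["left", "right"]),
                rng.choice(["left", "right", "none"]),
                float(rng.uniform(0, 500)),
            )
        )
    trials = make_trials(rows)
    vec = classify_trials(trials)
    for idx, row in trials.iterrows():
        assert vec.loc[idx] == classify_trial(
            row.target_side, row.first_saccade_direction, row.latency_ms
        )


def test_outcome_partition_is_exhaustive():
    rng = np.random.default_rng(3)
    trials = make_trials(
        [
            ("s", "on", rng.choice(["left", "right"]),
             rng.choice(["left", "right", "none"]), float(rng.uniform(0, 400)))
            for _ in range(500)
        ]
    )
    counts = classify_trials(trials).value_counts()
    assert counts.sum() == len(trials)
    assert set(counts.index) <= {"error", "correct", "anticipatory", "invalid"}


class TestSubjectSummary:
    def test_hand_counted_error_rate(self):
        # 4 errors, 5 correct, 1 anticipatory -> 4/9
        rows = (
            [("s", "on", "right", "right", 200.0)] * 4
            + [("s", "on", "right", "left", 250.0)] * 5
            + [("s", "on", "right", "left", 50.0)]
        )
        s = summarize_subject(make_trials(rows))
        assert s.error_rate == pytest.approx(4 / 9)
        assert s.n_valid == 9
        assert s.n_anticipatory == 1

    def test_all_correct_gives_zero(self):
        rows = [("s", "on", "right", "left", 300.0)] * 5
        assert summarize_subject(make_trials(rows)).error_rate == 0.0

    def test_all_anticipatory_is_undefined(self):
        rows = [("s", "on", "right", "left", 50.0)] * 5
        with pytest.raises(UndefinedSummaryError):
            summarize_subject(make_trials(rows))

    def test_mean_latency_over_correct_trials_only(self):
        rows = [
            ("s", "on", "right", "left", 300.0),
            ("s", "on", "right", "left", 400.0),
            ("s", "on", "right", "right", 9000.0),  # error latency ignored
        ]
        s = summarize_subject(make_trials(rows))
        assert s.mean_latency_correct == pytest.approx(350.0)

    def test_error_rate_invariant_to_trial_order(self):
        rng = np.random.default_rng(11)
        rows = [
            ("s", "on", "right", rng.choice(["left", "right"]),
             float(rng.uniform(50, 400)))
            for _ in range(100)
        ]
        trials = make_trials(rows)
        shuffled = trials.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert summarize_subject(trials).error_rate == pytest.approx(
            summarize_subject(shuffled).error_rate
        )


class TestChangeScores:
    def _summaries(self, per_subject):
        rows = []
        for subject, (err_on, err_off, lat_on, lat_off) in per_subject.items():
            rows += [
                {"subject": subject, "condition": "on", "error_rate": err_on,
                 "mean_latency_correct": lat_on, "n_valid": 100},
                {"subject": subject, "condition": "off", "error_rate": err_off,
                 "mean_latency_correct": lat_off, "n_valid": 100},
            ]
        return pd.DataFrame(rows).set_index(["subject", "condition"])

    def test_on_minus_off_sign_convention(self):
        # a decrease with DBS on must come out negative
        deltas = change_scores(self._summaries({"s1": (0.4, 0.5, 331.1, 355.1)}))
        assert deltas.loc["s1", "delta_error_rate"] == pytest.approx(-0.1)
        assert deltas.loc["s1", "delta_latency_ms"] == pytest.approx(-24.0)

    def test_identical_conditions_give_zero(self):
        deltas = change_scores(self._summaries({"s1": (0.3, 0.3, 300.0, 300.0)}))
        assert (deltas.loc["s1"] == 0).all()

    def test_subject_missing_condition_dropped_with_warning(self):
        summaries = self._summaries({"s1": (0.4, 0.5, 331.0, 355.0)})
        summaries = pd.concat(
            [summaries,
             pd.DataFrame(
                 [{"subject": "s2", "condition": "on", "error_rate": 0.2,
                   "mean_latency_correct": 300.0, "n_valid": 50}]
             ).set_index(["subject", "condition"])]
        )
        with pytest.warns(UserWarning, match="s2"):
            deltas = change_scores(summaries)
        assert list(deltas.index) == ["s1"]


class TestPairedT:
    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 30)
            on = rng.normal(size=n)
            off = rng.normal(size=n)
            res = paired_t(on, off)
            d = on - off
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert res.t == pytest.approx(t_ref, abs=1e-12)
            assert res.df == n - 1
            half = stats.t.ppf(0.975, n - 1) * d.std(ddof=1) / np.sqrt(n)
            assert res.ci95[0] == pytest.approx(d.mean() - half, abs=1e-12)
            assert res.p == pytest.approx(
                2 * stats.t.sf(abs(t_ref), n - 1), abs=1e-12
            )

    def test_identical_conditions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.t == 0.0
        assert res.ci95[0] == pytest.approx(-res.ci95[1])

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    def test_summary_form_agrees_with_sample_form(self):
        rng = np.random.default_rng(5)
        on, off = rng.normal(size=10), rng.normal(size=10)
        d = on - off
        a = paired_t(on, off)
        b = paired_t_from_summary(d.mean(), d.std(ddof=1), 10)
        assert a.t == pytest.approx(b.t) and a.ci95 == pytest.approx(b.ci95)


class TestLatencyDistribution:
    def test_cumulative_proportions_are_k_over_n(self):
        lats = [300.0, 120.0, 250.0, 180.0, 400.0, 220.0, 310.0, 150.0, 270.0, 199.0]
        trials = make_trials([("s", "on", "right", "left", l) for l in lats])
        table = latency_distribution(trials)
        assert list(table["latency_ms"]) == sorted(lats)
        assert list(table["cum_prop"]) == pytest.approx(
            [(k + 1) / 10 for k in range(10)]
        )

    def test_probit_of_median_is_zero(self):
        trials = make_trials([("s", "on", "right", "left", l) for l in (100.0, 200.0)])
        table = latency_distribution(trials)
        # cum 0.5 at the first of two points -> probit exactly 0
        assert table["probit"].iloc[0] == pytest.approx(0.0)

    def test_probit_finite_under_clipping(self):
        trials = make_trials([("s", "on", "right", "left", 200.0)] * 6)
        table = latency_distribution(trials)
        assert np.isfinite(table["probit"]).all()
        assert table["cum_prop"].is_monotonic_increasing

    def test_empty_class_gives_empty_table(self):
        trials = make_trials([("s", "on", "right", "left", 200.0)])
        assert latency_distribution(trials, condition="off").empty


def test_summarize_trials_groups_by_subject_and_condition():
    rows = []
    for subject in ("a", "b"):
        for condition in ("on", "off"):
            rows += [(subject, condition, "right", "left", 300.0)] * 3
            rows += [(subject, condition, "right", "right", 200.0)]
    summary = summarize_trials(make_trials(rows))
    assert len(summary) == 4
    assert summary["error_rate"].unique() == pytest.approx([0.25])
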