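"""Feasibility metrics against direct brute-force oracles and printed-count checks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from swaft.analytics import (
    FlowCounts,
    activity_summary,
    adherence_table,
    completion_table,
    daily_total,
    daily_totals,
    delta_metrics,
    exceedance,
    exceedance_table,
    flow_rates,
    weekday_count,
)

from .conftest import MONDAY


def weekdays_from(start: dt.date, n: int) -> list[dt.date]:
    days, d = [], start
    while len(days) < n:
        if d.weekday() < 5:
            days.append(d)
        d += dt.timedelta(days=1)
    return days


def mini_registry(groups: dict[str, str], start: dt.date = MONDAY) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": pid, "group": g, "intervention_start": start, "discharge_date": None}
         for pid, g in groups.items()],
        columns=["id", "group", "intervention_start", "discharge_date"],
    )


class TestDailyTotal:
    def test_period_five_excluded(self):
        result = daily_total({1: 10, 2: 20, 3: 30, 4: 40, 5: 99})
        assert result.total == 100 and not result.partial and not result.missing

    def test_all_analysis_periods_missing(self):
        result = daily_total({5: 99})
        assert result.total == 0 and result.missing

    def test_partial_day_flagged(self):
        result = daily_total({1: 10, 2: 20})
        assert result.total == 30 and result.partial and not result.missing


class TestExceedance:
    def test_strict_exceedance_counts(self):
        assert exceedance([100, 120, 90, 101]) == (2, 3)

    def test_equality_never_counts(self):
        assert exceedance([100, 100, 100, 100]) == (0, 3)

    def test_no_days_errors(self):
        with pytest.raises(ValueError):
            exceedance([])

    def test_group_rates_use_both_denominators(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 5)
        rows = []
        for pid, totals in (("a", [100, 120, 130, 90, 140]), ("b", [50, 60, 40, 70, 80])):
            for day, total in zip(days, totals):
                rows.append((pid, day, 1, total, True))
        records = make_epoch_frame(rows)
        table = exceedance_table(records, mini_registry({"a": "feedback", "b": "feedback"}))
        row = table.loc["feedback"]
        # a exceeds on 3 of 4 post-baseline days, b on 3 of 4
        assert row["days_exceeding_baseline"] == 6
        assert row["expected_days"] == 10 and row["actual_days"] == 10
        assert row["rate_vs_expected"] == pytest.approx(60.0)
        assert row["days_exceeding_baseline"] <= row["actual_days"]


class TestFlowRates:
    def test_printed_count_reproduction(self):
        fc = FlowCounts(admitted=470, recruited=51, valid=50,
                        completed_discharge=39, completed_followup=24)
        rates = flow_rates(fc)
        assert rates == {
            "recruitment": 11,
            "retention_discharge": 78,
            "retention_followup": 48,
            "followup_among_discharged": 62,
        }

    def test_zero_denominators_do_not_raise(self):
        fc = FlowCounts(0, 0, 0, 0, 0)
        assert flow_rates(fc) == {
            "recruitment": 0, "retention_discharge": 0,
            "retention_followup": 0, "followup_among_discharged": 0,
        }

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            FlowCounts(admitted=10, recruited=20, valid=5,
                       completed_discharge=3, completed_followup=1)


def oracle_adherence_categories(records: pd.DataFrame) -> dict[int, int]:
    """Brute-force per-day count of worn analysis periods."""
    counts = {4: 0, 3: 0, 2: 0, 1: 0, 0: 0}
    for (_, _), day in records.groupby(["patient_id", "date"]):
        n_worn = int(day[(day["period"] <= 4) & day["worn"]]["period"].nunique())
        counts[n_worn] += 1
    return counts


class TestAdherence:
    def test_empty_record_set_all_zero(self, make_epoch_frame):
        table = adherence_table(make_epoch_frame([]), mini_registry({}))
        assert table.empty

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_categorisation(self, seed, make_epoch_frame):
        rng = np.random.default_rng(seed)
        days = weekdays_from(MONDAY, 8)
        rows = []
        for pid in ("a", "b", "c"):
            for day in days:
                for period in range(1, 6):
                    if rng.random() < 0.8:
                        rows.append((pid, day, period, float(rng.uniform(0, 50)),
                                     bool(rng.random() < 0.7)))
        records = make_epoch_frame(rows)
        table = adherence_table(
            records, mini_registry({"a": "feedback", "b": "feedback", "c": "feedback"})
        )
        expected = oracle_adherence_categories(records)
        row = table.loc["feedback"]
        for k in (4, 3, 2, 1):
            assert row[f"worn_{k}"] == expected[k]
        assert row["worn_ge1"] == sum(expected[k] for k in (4, 3, 2, 1))

    def test_each_recorded_day_in_exactly_one_category(self, make_epoch_frame):
        rng = np.random.default_rng(99)
        days = weekdays_from(MONDAY, 10)
        rows = [("a", day, p, 1.0, bool(rng.random() < 0.5))
                for day in days for p in range(1, 6)]
        records = make_epoch_frame(rows)
        table = adherence_table(records, mini_registry({"a": "observation"}))
        row = table.loc["observation"]
        expected = oracle_adherence_categories(records)
        assert (row["worn_4"] + row["worn_3"] + row["worn_2"] + row["worn_1"]
                + expected[0]) == row["actual_days"]

    def test_weekend_recording_can_push_actual_above_expected(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 5)
        saturday = MONDAY + dt.timedelta(days=5)
        rows = [("a", day, p, 1.0, True) for day in days for p in range(1, 5)]
        rows += [("a", saturday, p, 1.0, True) for p in range(1, 5)]
        records = make_epoch_frame(rows)
        # trial span ends on the last weekday -> expected 5 weekdays, actual 6 days
        table = adherence_table(records, mini_registry({"a": "feedback"}))
        row = table.loc["feedback"]
        assert row["expected_days"] == 5 and row["actual_days"] == 6
        assert row["worn_ge1_pct_expected"] == pytest.approx(120.0)


def oracle_completion(assessments, registry, measures, timepoint):
    """Per-measure percentage scan and all-measures count, by direct loops."""
    out = {}
    for group, reg_g in registry.groupby("group"):
        pids = list(reg_g["id"])
        pcts = []
        for m in measures:
            n_done = sum(
                bool(assessments[
                    (assessments["patient_id"] == pid)
                    & (assessments["timepoint"] == timepoint)
                    & (assessments["measure"] == m)
                    & assessments["completed"]
                ].shape[0])
                for pid in pids
            )
            pcts.append(int(np.floor(100 * n_done / len(pids) + 0.5)))
        n_full = sum(
            all(
                assessments[
                    (assessments["patient_id"] == pid)
                    & (assessments["timepoint"] == timepoint)
                    & (assessments["measure"] == m)
                    & assessments["completed"]
                ].shape[0] > 0
                for m in measures
            )
            for pid in pids
        )
        out[group] = (n_full, min(pcts), max(pcts))
    return out


class TestCompletion:
    @staticmethod
    def _random_assessments(seed, pids, measures):
        rng = np.random.default_rng(seed)
        rows = []
        for pid in pids:
            for tp in ("baseline", "discharge"):
                for m in measures:
                    rows.append({"patient_id": pid, "timepoint": tp, "measure": m,
                                 "completed": bool(rng.random() < 0.7)})
        return pd.DataFrame(rows)

    def test_full_completion_gives_group_size_and_100s(self):
        registry = mini_registry({"a": "feedback", "b": "feedback"})
        measures = ("m1", "m2")
        rows = [{"patient_id": pid, "timepoint": "baseline", "measure": m, "completed": True}
                for pid in ("a", "b") for m in measures]
        table = completion_table(
            pd.DataFrame(rows), registry,
            measure_sets={"set": (("baseline",), measures)},
        )
        row = table.loc[("feedback", "set", "baseline")]
        assert row["n_full"] == 2
        assert row["range_min_pct"] == row["range_max_pct"] == 100

    def test_one_missing_measure_decrements_full_count(self):
        registry = mini_registry({"a": "feedback", "b": "feedback"})
        measures = ("m1", "m2")
        rows = [{"patient_id": pid, "timepoint": "baseline", "measure": m, "completed": True}
                for pid in ("a", "b") for m in measures]
        rows[-1]["completed"] = False
        table = completion_table(
            pd.DataFrame(rows), registry,
            measure_sets={"set": (("baseline",), measures)},
        )
        row = table.loc[("feedback", "set", "baseline")]
        assert row["n_full"] == 1
        assert (row["range_min_pct"], row["range_max_pct"]) == (50, 100)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        registry = mini_registry({"a": "feedback", "b": "feedback", "c": "no_feedback"})
        measures = ("m1", "m2", "m3")
        assessments = self._random_assessments(seed, ("a", "b", "c"), measures)
        table = completion_table(
            assessments, registry,
            measure_sets={"set": (("baseline",), measures)},
        )
        expected = oracle_completion(assessments, registry, measures, "baseline")
        for group, (n_full, lo, hi) in expected.items():
            row = table.loc[(group, "set", "baseline")]
            assert (row["n_full"], row["range_min_pct"], row["range_max_pct"]) == (n_full, lo, hi)


def oracle_quantiles(values):
    """Inclusive linear-interpolation quartiles on a sorted copy."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.5), q(0.75)


class TestActivitySummary:
    def test_constant_totals(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 5)
        rows = [(pid, days[0], p, 12.5, True) for pid in "abcd" for p in range(1, 5)]
        records = make_epoch_frame(rows)
        table = activity_summary(records, mini_registry(dict.fromkeys("abcd", "feedback")))
        row = table.loc[("feedback", 1)]
        assert (row["median"], row["q1"], row["q3"], row["n"]) == (50.0, 50.0, 50.0, 4)

    def test_single_patient_group(self, make_epoch_frame):
        records = make_epoch_frame([("a", MONDAY, 1, 80.0, True)])
        table = activity_summary(records, mini_registry({"a": "observation"}))
        row = table.loc[("observation", 1)]
        assert row["median"] == 80.0 and row["n"] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sorted_list_quantile_oracle(self, seed, make_epoch_frame):
        rng = np.random.default_rng(seed)
        pids = [f"p{i}" for i in range(int(rng.integers(3, 12)))]
        rows = [(pid, MONDAY, p, float(rng.uniform(0, 100)), True)
                for pid in pids for p in range(1, 5)]
        records = make_epoch_frame(rows)
        table = activity_summary(records, mini_registry(dict.fromkeys(pids, "feedback")))
        totals = daily_totals(records)["total"].tolist()
        q1, med, q3 = oracle_quantiles(totals)
        row = table.loc[("feedback", 1)]
        assert row["q1"] == pytest.approx(q1)
        assert row["median"] == pytest.approx(med)
        assert row["q3"] == pytest.approx(q3)

    def test_day_index_is_weekday_index(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 6)  # spans a weekend
        rows = [("a", d, 1, float(i), True) for i, d in enumerate(days)]
        records = make_epoch_frame(rows)
        table = activity_summary(records, mini_registry({"a": "feedback"}),
                                 day_indices=(1, 5, 6))
        assert table.loc[("feedback", 6)]["median"] == 5.0  # Monday of week 2


class TestDeltaMetrics:
    def test_constant_activity_gives_zero_deltas(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 4)
        rows = [("a", d, p, 25.0, True) for d in days for p in range(1, 5)]
        table = delta_metrics(make_epoch_frame(rows), MONDAY)
        post = table.query("day_index > 1")
        assert (post["delta_baseline"] == 0).all()
        assert (post["delta_previous"] == 0).all()

    def test_strictly_increasing_activity_gives_positive_deltas(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 5)
        rows = [("a", d, p, 10.0 * (i + 1), True)
                for i, d in enumerate(days) for p in range(1, 5)]
        table = delta_metrics(make_epoch_frame(rows), MONDAY)
        post = table.query("day_index > 1")
        assert (post["delta_baseline"] > 0).all()
        assert (post["delta_previous"] > 0).all()

    def test_missing_days_propagate_as_nan(self, make_epoch_frame):
        days = weekdays_from(MONDAY, 3)
        rows = [("a", days[0], 1, 10.0, True), ("a", days[2], 1, 30.0, True)]
        table = delta_metrics(make_epoch_frame(rows), MONDAY)
        assert np.isnan(table.loc[(1, 2)]["as_score"])
        assert np.isnan(table.loc[(1, 3)]["delta_previous"])  # previous day missing
        assert table.loc[(1, 3)]["delta_baseline"] == 20.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_subtraction_oracle(self, seed, make_epoch_frame):
        rng = np.random.default_rng(seed)
        days = weekdays_from(MONDAY, 6)
        rows = [("a", d, p, float(rng.uniform(0, 100)), True)
                for d in days for p in range(1, 5)]
        frame = make_epoch_frame(rows)
        table = delta_metrics(frame, MONDAY)
        by_period = {
            (p, i + 1): v
            for p in range(1, 5)
            for i, v in enumerate(
                frame[frame["period"] == p].sort_values("date")["activity_score"]
            )
        }
        for (p, d), row in table.iterrows():
            assert row["delta_baseline"] == pytest.approx(by_period[(p, d)] - by_period[(p, 1)])
            if d > 1:
                assert row["delta_previous"] == pytest.approx(
                    by_period[(p, d)] - by_period[(p, d - 1)]
                )


class TestWeekdayCount:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (MONDAY, MONDAY, 1),
            (MONDAY, MONDAY + dt.timedelta(days=4), 5),
            (MONDAY, MONDAY + dt.timedelta(days=6), 5),   # spans the weekend
            (MONDAY, MONDAY + dt.timedelta(days=7), 6),
            (MONDAY + dt.timedelta(days=5), MONDAY + dt.timedelta(days=6), 0),
        ],
    )
    def test_inclusive_weekday_span(self, start, end, expected):
        assert weekday_count(start, end) == expected
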