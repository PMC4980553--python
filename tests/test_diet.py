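"""Diet-arm statistics: day-level matching, window curves, subgroup tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emaval import (
    NAMED_FOOD_GROUPS,
    day_match_rates,
    diet_mixed_logit,
    subgroup_chisq,
    window_match_curve,
    window_sens_spec,
)
from conftest import make_prompts, make_recalls


def _days(pairs):
    return pd.DataFrame(
        [{"participant_id": p, "date": pd.Timestamp(d)} for p, d in pairs]
    )


class TestDayMatchRates:
    def test_worked_example_four_reports_three_recalls(self):
        # 4 momentary fruit/vegetable endorsements vs 3 recall instances:
        # 3 matches of a potential 4 -> 75%
        prompts = make_prompts(
            [("P001", f"2023-03-01 {h}:00", "fruits_vegetables", "sedentary") for h in (9, 12, 15, 19)]
        )
        recalls = make_recalls(
            [("P001", "2023-03-01", t, "fruits_vegetables", 2000.0) for t in ("09:30", "13:00", "18:00")]
        )
        res = day_match_rates(prompts, recalls, _days([("P001", "2023-03-01")]))
        row = res.per_group.set_index("food_group").loc["fruits_vegetables"]
        assert row["n_mema"] == 4 and row["n_matched"] == 3
        assert row["match_rate"] == pytest.approx(75.0)

    def test_worked_example_converse_full_match(self):
        prompts = make_prompts(
            [("P001", f"2023-03-01 {h}:00", "fruits_vegetables", "sedentary") for h in (9, 12, 15)]
        )
        recalls = make_recalls(
            [("P001", "2023-03-01", t, "fruits_vegetables", 2000.0)
             for t in ("09:30", "13:00", "18:00", "20:00")]
        )
        res = day_match_rates(prompts, recalls, _days([("P001", "2023-03-01")]))
        row = res.per_group.set_index("food_group").loc["fruits_vegetables"]
        assert row["n_mema"] == 3 and row["n_matched"] == 3
        assert row["match_rate"] == pytest.approx(100.0)

    def test_group_never_endorsed_reports_missing_rate(self):
        prompts = make_prompts([("P001", "2023-03-01 09:00", "sweets", "sedentary")])
        recalls = make_recalls([("P001", "2023-03-01", "09:30", "entree", 2000.0)])
        res = day_match_rates(prompts, recalls, _days([("P001", "2023-03-01")]))
        entree = res.per_group.set_index("food_group").loc["entree"]
        assert entree["n_mema"] == 0 and np.isnan(entree["match_rate"])

    def test_random_counts_equal_brute_force_min_summation(self):
        rng = np.random.default_rng(23)
        prompt_rows, recall_rows, day_keys = [], [], []
        counts = {}
        for d in range(15):
            pid, date = f"P{d % 5:03d}", f"2023-03-{d + 1:02d}"
            day_keys.append((pid, date))
            for g in NAMED_FOOD_GROUPS:
                m, r = rng.integers(0, 4), rng.integers(0, 4)
                counts[(pid, date, g)] = (m, r)
                for k in range(m):
                    prompt_rows.append((pid, f"{date} 09:{k:02d}", g, "sedentary"))
                for k in range(r):
                    recall_rows.append((pid, date, f"12:{k:02d}", g, 2000.0))
        res = day_match_rates(
            make_prompts(prompt_rows), make_recalls(recall_rows), _days(day_keys)
        )
        for g in NAMED_FOOD_GROUPS:
            n_mema = sum(m for (p, d, gg), (m, r) in counts.items() if gg == g)
            n_matched = sum(min(m, r) for (p, d, gg), (m, r) in counts.items() if gg == g)
            row = res.per_group.set_index("food_group").loc[g]
            assert row["n_mema"] == n_mema and row["n_matched"] == n_matched

    def test_dominance_gives_full_match(self):
        # recall counts >= momentary counts on every day -> 100% everywhere
        prompts = make_prompts(
            [("P001", "2023-03-01 09:00", "sweets;entree", "sedentary"),
             ("P001", "2023-03-02 09:00", "sweets", "sedentary")]
        )
        recalls = make_recalls(
            [("P001", "2023-03-01", "10:00", "sweets", 2000.0),
             ("P001", "2023-03-01", "11:00", "sweets", 2000.0),
             ("P001", "2023-03-01", "12:00", "entree", 2000.0),
             ("P001", "2023-03-02", "10:00", "sweets", 2000.0)]
        )
        res = day_match_rates(
            prompts, recalls, _days([("P001", "2023-03-01"), ("P001", "2023-03-02")])
        )
        rates = res.per_group.dropna(subset=["match_rate"])["match_rate"]
        assert (rates == 100.0).all()


class TestWindowCurve:
    def test_recall_at_report_time_matches_every_width(self):
        prompts = make_prompts([("P001", "2023-03-01 12:00", "sweets", "sedentary")])
        recalls = make_recalls([("P001", "2023-03-01", "12:00", "sweets", 2000.0)])
        curve = window_match_curve(prompts, recalls, grid=[6, 12, 480])
        sweets = curve[curve["food_group"] == "sweets"]
        assert (sweets["n_matched"] == 1).all()

    def test_seven_minute_offset_boundary(self):
        prompts = make_prompts([("P001", "2023-03-01 12:00", "sweets", "sedentary")])
        recalls = make_recalls([("P001", "2023-03-01", "12:07", "sweets", 2000.0)])
        curve = window_match_curve(prompts, recalls, grid=[6, 12]).set_index("w")
        sweets = curve[curve["food_group"] == "sweets"]
        assert sweets.loc[6, "n_matched"] == 0
        assert sweets.loc[12, "n_matched"] == 1

    def test_empty_grid_rejected(self):
        prompts = make_prompts([("P001", "2023-03-01 12:00", "sweets", "sedentary")])
        recalls = make_recalls([("P001", "2023-03-01", "12:00", "sweets", 2000.0)])
        with pytest.raises(ValueError):
            window_match_curve(prompts, recalls, grid=[])

    def test_random_offsets_equal_brute_force_all_pairs(self):
        rng = np.random.default_rng(31)
        prompt_rows, recall_rows = [], []
        for i in range(40):
            pid = f"P{i % 4:03d}"
            ph, pm = rng.integers(9, 21), rng.integers(0, 60)
            g = rng.choice(NAMED_FOOD_GROUPS)
            prompt_rows.append((pid, f"2023-03-01 {ph:02d}:{pm:02d}", g, "sedentary"))
            rh, rm = rng.integers(8, 23), rng.integers(0, 60)
            recall_rows.append((pid, "2023-03-01", f"{rh:02d}:{rm:02d}",
                                rng.choice(NAMED_FOOD_GROUPS), 2000.0))
        prompts, recalls = make_prompts(prompt_rows), make_recalls(recall_rows)
        grid = [6, 30, 120, 480]
        curve = window_match_curve(prompts, recalls, grid=grid)

        for g in NAMED_FOOD_GROUPS:
            sub_p = prompts[prompts["food_groups"] == g]
            sub_r = recalls[recalls["food_group"] == g]
            for w in grid:
                matched = 0
                for _, p in sub_p.iterrows():
                    hits = sub_r[
                        (sub_r["participant_id"] == p["participant_id"])
                        & (abs(sub_r["timestamp"] - p["timestamp"]) <= pd.Timedelta(minutes=w))
                    ]
                    matched += int(len(hits) > 0)
                row = curve[(curve["food_group"] == g) & (curve["w"] == w)].iloc[0]
                assert row["n_matched"] == matched

    def test_ppv_monotone_in_width(self):
        rng = np.random.default_rng(5)
        prompt_rows = [
            (f"P{i % 3:03d}", f"2023-03-01 {rng.integers(9, 21):02d}:{rng.integers(0, 60):02d}",
             rng.choice(NAMED_FOOD_GROUPS), "sedentary")
            for i in range(30)
        ]
        recall_rows = [
            (f"P{i % 3:03d}", "2023-03-01", f"{rng.integers(8, 23):02d}:{rng.integers(0, 60):02d}",
             rng.choice(NAMED_FOOD_GROUPS), 2000.0)
            for i in range(30)
        ]
        curve = window_match_curve(make_prompts(prompt_rows), make_recalls(recall_rows))
        for _, sub in curve.groupby("food_group"):
            ppv = sub.sort_values("w")["n_matched"].to_numpy()
            assert (np.diff(ppv) >= 0).all()


class TestWindowSensSpec:
    def test_counts_conserve_occasions(self):
        rng = np.random.default_rng(7)
        prompt_rows = [
            (f"P{i % 3:03d}", f"2023-03-01 {rng.integers(9, 21):02d}:{rng.integers(0, 60):02d}",
             rng.choice(list(NAMED_FOOD_GROUPS) + [""]), "sedentary")
            for i in range(25)
        ]
        recall_rows = [
            (f"P{i % 3:03d}", "2023-03-01", f"{rng.integers(8, 23):02d}:{rng.integers(0, 60):02d}",
             rng.choice(NAMED_FOOD_GROUPS), 2000.0)
            for i in range(20)
        ]
        prompts, recalls = make_prompts(prompt_rows), make_recalls(recall_rows)
        ss = window_sens_spec(prompts, recalls, grid=[6, 60, 300])
        for _, row in ss.iterrows():
            assert row["tp"] + row["fp"] + row["fn"] + row["tn"] == len(prompts)

    def test_random_fixture_equals_brute_force_tally(self):
        rng = np.random.default_rng(41)
        prompt_rows = [
            (f"P{i % 2:03d}", f"2023-03-01 {rng.integers(9, 21):02d}:{rng.integers(0, 60):02d}",
             rng.choice(list(NAMED_FOOD_GROUPS) + ["", ""]), "sedentary")
            for i in range(30)
        ]
        recall_rows = [
            (f"P{i % 2:03d}", "2023-03-01", f"{rng.integers(8, 23):02d}:{rng.integers(0, 60):02d}",
             rng.choice(NAMED_FOOD_GROUPS), 2000.0)
            for i in range(25)
        ]
        prompts, recalls = make_prompts(prompt_rows), make_recalls(recall_rows)
        grid = [30, 240]
        ss = window_sens_spec(prompts, recalls, grid=grid)
        for g in NAMED_FOOD_GROUPS:
            for w in grid:
                tp = fp = fn = tn = 0
                for _, p in prompts.iterrows():
                    endorsed = g in p["food_groups"].split(";")
                    sub_r = recalls[
                        (recalls["participant_id"] == p["participant_id"])
                        & (recalls["food_group"] == g)
                        & (abs(recalls["timestamp"] - p["timestamp"]) <= pd.Timedelta(minutes=w))
                    ]
                    ref = len(sub_r) > 0
                    tp += endorsed and ref
                    fp += endorsed and not ref
                    fn += (not endorsed) and ref
                    tn += (not endorsed) and not ref
                row = ss[(ss["food_group"] == g) & (ss["w"] == w)].iloc[0]
                assert (row["tp"], row["fp"], row["fn"], row["tn"]) == (tp, fp, fn, tn)

    def test_never_endorsed_group_has_zero_sensitivity(self):
        prompts = make_prompts(
            [("P001", "2023-03-01 12:00", "", "sedentary"),
             ("P001", "2023-03-01 13:00", "sweets", "sedentary")]
        )
        recalls = make_recalls([("P001", "2023-03-01", "12:30", "entree", 2000.0)])
        ss = window_sens_spec(prompts, recalls, grid=[60])
        entree = ss[ss["food_group"] == "entree"].iloc[0]
        assert entree["sensitivity"] == 0.0

    def test_displaced_recall_times_drive_directional_tradeoff(self):
        # recall instances are time-displaced copies of momentary reports:
        # widening the window turns more non-endorsed prompts into
        # reference-positives, so sensitivity falls while specificity rises
        # (the reference set shrinks on the negative side)
        rng = np.random.default_rng(3)
        prompt_rows, recall_rows = [], []
        for i in range(80):
            pid = f"P{i % 20:03d}"
            h, m = int(rng.integers(9, 20)), int(rng.integers(0, 60))
            endorsed = rng.random() < 0.3
            prompt_rows.append((pid, f"2023-03-01 {h:02d}:{m:02d}",
                                "sweets" if endorsed else "", "sedentary"))
            if endorsed:
                disp = int(rng.normal(0, 60))
                tot = min(max(h * 60 + m + disp, 0), 1439)
                recall_rows.append((pid, "2023-03-01", f"{tot // 60:02d}:{tot % 60:02d}",
                                    "sweets", 2000.0))
        ss = window_sens_spec(
            make_prompts(prompt_rows), make_recalls(recall_rows), grid=[30, 120]
        )
        sweets = ss[ss["food_group"] == "sweets"].set_index("w")
        assert sweets.loc[120, "sensitivity"] <= sweets.loc[30, "sensitivity"]
        assert sweets.loc[120, "specificity"] >= sweets.loc[30, "specificity"]


class TestSubgroupChisq:
    @staticmethod
    def _per_day(matched_a, unmatched_a, matched_b, unmatched_b, group="sweets"):
        rows = []
        for pid, m, u in (("A", matched_a, unmatched_a), ("B", matched_b, unmatched_b)):
            rows.append({"participant_id": pid, "date": pd.Timestamp("2023-03-01"),
                         "food_group": group, "n_mema": m + u, "n_recall": m, "n_matched": m})
        return pd.DataFrame(rows)

    def test_two_by_two_equals_closed_form(self):
        # uncorrected chi-square for (30,10 / 20,20):
        # expected cells 25/15/25/15 -> chi2 = 16/3
        per_day = self._per_day(30, 10, 20, 20)
        participants = pd.DataFrame({"participant_id": ["A", "B"], "gender": ["female", "male"]})
        res = subgroup_chisq(per_day, participants, "gender", groups=("sweets",))
        expected = stats.chi2_contingency([[30, 10], [20, 20]], correction=False).statistic
        assert res.iloc[0]["chi2"] == pytest.approx(16 / 3)
        assert res.iloc[0]["chi2"] == pytest.approx(expected)
        assert res.iloc[0]["df"] == 1

    def test_null_case_not_significant(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(100):
            pid = f"P{i:03d}"
            m = rng.binomial(10, 0.7)
            rows.append({"participant_id": pid, "date": pd.Timestamp("2023-03-01"),
                         "food_group": "sweets", "n_mema": 10, "n_recall": m, "n_matched": m})
        per_day = pd.DataFrame(rows)
        participants = pd.DataFrame(
            {"participant_id": [f"P{i:03d}" for i in range(100)],
             "gender": ["female" if i % 2 else "male" for i in range(100)]}
        )
        res = subgroup_chisq(per_day, participants, "gender", groups=("sweets",))
        assert res.iloc[0]["p"] > 0.05

    def test_planted_gap_detected(self):
        # 30-point match-rate gap at n=2,000 endorsements -> p < 0.001
        rng = np.random.default_rng(4)
        rows = []
        for i in range(200):
            pid = f"P{i:03d}"
            p_match = 0.85 if i % 2 else 0.55
            m = rng.binomial(10, p_match)
            rows.append({"participant_id": pid, "date": pd.Timestamp("2023-03-01"),
                         "food_group": "sweets", "n_mema": 10, "n_recall": m, "n_matched": m})
        per_day = pd.DataFrame(rows)
        participants = pd.DataFrame(
            {"participant_id": [f"P{i:03d}" for i in range(200)],
             "gender": ["female" if i % 2 else "male" for i in range(200)]}
        )
        res = subgroup_chisq(per_day, participants, "gender", groups=("sweets",))
        assert res.iloc[0]["p"] < 0.001

    def test_low_expected_cells_flagged(self):
        per_day = self._per_day(1, 0, 0, 1)
        participants = pd.DataFrame({"participant_id": ["A", "B"], "gender": ["female", "male"]})
        res = subgroup_chisq(per_day, participants, "gender", groups=("sweets",))
        assert not res.iloc[0]["reliable"]


class TestDietMixedLogit:
    def test_independent_data_or_near_one(self):
        rng = np.random.default_rng(9)
        n_part, n_days = 150, 10
        days, prompt_rows, recall_rows = [], [], []
        for i in range(n_part):
            pid = f"P{i:03d}"
            for d in range(n_days):
                date = pd.Timestamp("2023-03-01") + pd.Timedelta(days=d)
                days.append((pid, date.strftime("%Y-%m-%d")))
                if rng.random() < 0.4:
                    prompt_rows.append((pid, f"{date:%Y-%m-%d} 10:00", "sweets", "sedentary"))
                if rng.random() < 0.5:
                    recall_rows.append((pid, f"{date:%Y-%m-%d}", "12:00", "sweets", 2000.0))
        res = diet_mixed_logit(
            make_prompts(prompt_rows), make_recalls(recall_rows), _days(days), groups=("sweets",)
        )
        row = res.iloc[0]
        assert row["converged"]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]
        assert 0.6 < row["or"] < 1.6
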