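"""Weekly classification tests: participation filter boundary, the
percentage-change formula, fluctuation and readiness binning, and
transition bookkeeping against a hand-classified fixture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import locoeff
from locoeff.errors import ConfigurationError, UndefinedChangeError
from locoeff.periodization import FLUCTUATION_CATEGORIES


def _attendance_sessions(counts: dict[str, int], n_dates: int = 100):
    rows = [
        {"player_id": pid, "date": f"2022-{1 + d // 28:02d}-{d % 28 + 1:02d}", "session_type": "training"}
        for pid, n in counts.items()
        for d in range(n)
    ]
    schedule = [f"2022-{1 + d // 28:02d}-{d % 28 + 1:02d}" for d in range(n_dates)]
    return pd.DataFrame(rows), schedule


class TestParticipation:
    def test_boundary_at_sixty_percent(self):
        sessions, schedule = _attendance_sessions({"A": 59, "B": 60, "C": 100})
        retained, excluded = locoeff.filter_participation(sessions, schedule, 0.60)
        assert set(retained["player_id"]) == {"B", "C"}
        assert set(excluded) == {"A"}
        assert excluded["A"] == pytest.approx(0.59)

    def test_empty_schedule_rejected(self):
        sessions, _ = _attendance_sessions({"A": 10})
        with pytest.raises(ConfigurationError):
            locoeff.filter_participation(sessions, [], 0.60)


class TestPctChange:
    def test_halving_is_minus_fifty(self):
        # weekly high-speed distance falling 200 m -> 100 m: -50%
        assert locoeff.pct_change(200.0, 100.0) == -50.0

    def test_identity_is_zero(self):
        assert locoeff.pct_change(1000.0, 1000.0) == 0.0

    def test_thirty_percent_rise(self):
        assert locoeff.pct_change(1000.0, 1300.0) == pytest.approx(30.0)

    def test_zero_base_is_undefined(self):
        with pytest.raises(UndefinedChangeError):
            locoeff.pct_change(0.0, 100.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(1e-3, 1e6), x=st.floats(-99.0, 500.0))
    def test_round_trip(self, a, x):
        assert locoeff.pct_change(a, a * (1 + x / 100.0)) == pytest.approx(x, abs=1e-6)


class TestClassifyFluctuation:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (-50.0, "large_decrease"),
            (-30.0, "moderate_decrease"),
            (-10.0, "no_variation"),
            (0.0, "no_variation"),
            (10.0, "no_variation"),
            (10.5, "moderate_increase"),
            (30.0, "moderate_increase"),
            (30.5, "large_increase"),
        ],
    )
    def test_boundaries(self, pct, expected):
        assert locoeff.classify_fluctuation(pct) == expected

    def test_exhaustive_sweep_total_and_monotone(self):
        order = {c: i for i, c in enumerate(FLUCTUATION_CATEGORIES)}
        prev = -1
        for pct in range(-100, 101):
            cat = locoeff.classify_fluctuation(float(pct))
            assert cat in order  # total: every value maps to exactly one bin
            assert order[cat] >= prev
            prev = order[cat]

    @settings(derandomize=True, max_examples=300)
    @given(p1=st.floats(-1000, 1000), p2=st.floats(-1000, 1000))
    def test_monotone_in_category_order(self, p1, p2):
        order = {c: i for i, c in enumerate(FLUCTUATION_CATEGORIES)}
        lo, hi = sorted([p1, p2])
        assert order[locoeff.classify_fluctuation(lo)] <= order[locoeff.classify_fluctuation(hi)]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            locoeff.classify_fluctuation(float("nan"))


class TestReadiness:
    @pytest.mark.parametrize(
        "lei, expected",
        [(-0.51, "bad"), (-0.5, "normal"), (0.0, "normal"), (0.5, "normal"), (0.51, "good")],
    )
    def test_cutoffs(self, lei, expected):
        assert locoeff.classify_readiness(lei) == expected

    def test_partition_covers_reals(self):
        for lei in np.linspace(-3, 3, 1201):
            assert locoeff.classify_readiness(float(lei)) in ("bad", "normal", "good")


class TestLeiVariation:
    @pytest.mark.parametrize(
        "w, w1, expected", [(0.2, 0.2, 0.0), (-0.8, 0.1, 0.9), (0.5, -0.5, -1.0)]
    )
    def test_signed_difference(self, w, w1, expected):
        assert locoeff.lei_variation(w, w1) == pytest.approx(expected)


class TestWeeklySummaries:
    def test_mean_lei_and_readiness(self):
        daily = pd.DataFrame(
            {
                "player_id": ["P1"] * 3 + ["P2"] * 2,
                "date": ["2022-01-03", "2022-01-04", "2022-01-05", "2022-01-03", "2022-01-04"],
                "lei": [0.8, 0.7, 0.9, -0.6, -0.6],
            }
        )
        sessions = pd.DataFrame(
            {
                "player_id": daily["player_id"],
                "date": daily["date"],
                "session_type": "training",
                "total_distance": [5000.0] * 5,
                "dist_gt_25_2": [100.0] * 5,
                "n_acc_gt_3_5": [10] * 5,
                "n_dec_lt_m3_5": [8] * 5,
            }
        )
        weeks = locoeff.weekly_summaries(daily, sessions)
        w = weeks.set_index("player_id")
        assert w.loc["P1", "weekly_lei"] == pytest.approx(0.8)
        assert w.loc["P1", "readiness"] == "good"
        assert w.loc["P2", "weekly_lei"] == pytest.approx(-0.6)
        assert w.loc["P2", "readiness"] == "bad"
        assert w.loc["P1", "total_distance"] == 15000.0
        assert w.loc["P1", "mechanical_load"] == 54
        assert (weeks["week_index"] == 0).all()  # 2022-01-03 is a Monday


class TestRollingView:
    def test_trailing_seven_day_sum(self):
        sessions = pd.DataFrame(
            {
                "player_id": "P1",
                "date": ["2022-01-03", "2022-01-05", "2022-01-10", "2022-01-11"],
                "session_type": "training",
                "total_distance": [1000.0, 2000.0, 4000.0, 8000.0],
                "dist_gt_25_2": [10.0, 20.0, 40.0, 80.0],
                "n_acc_gt_3_5": [1, 2, 4, 8],
                "n_dec_lt_m3_5": [0, 0, 0, 0],
            }
        )
        rolled = locoeff.periodization.rolling_weekly_loads(sessions).set_index("date")
        # Jan 10 window covers Jan 4..10 -> sessions on the 5th and 10th
        assert rolled.loc["2022-01-10", "total_distance"] == 6000.0
        # Jan 11 window covers Jan 5..11 -> the 5th, 10th and 11th
        assert rolled.loc["2022-01-11", "total_distance"] == 14000.0
        assert rolled.loc["2022-01-11", "mechanical_load"] == 14


class TestBuildTransitions:
    def test_counts_and_gaps(self, toy_weeks):
        trans = locoeff.build_transitions(toy_weeks)
        by_player = trans.groupby("player_id").size().to_dict()
        # A: weeks 0..4 complete -> 4 pairs; B: gap at week 2 -> only (0,1);
        # C: week 1 short -> no pairs
        assert by_player == {"A": 4, "B": 1}

    def test_categories_match_hand_classification(self, toy_weeks):
        trans = locoeff.build_transitions(toy_weeks).set_index(["player_id", "week_from"])
        expected = {
            ("A", 0): ("large_decrease", "no_variation", "moderate_increase"),
            ("A", 1): ("large_increase", "moderate_decrease", "no_variation"),
            ("A", 2): ("no_variation", "no_variation", "large_decrease"),
            ("A", 3): ("no_variation", "moderate_increase", "moderate_increase"),
            ("B", 0): ("moderate_increase", "no_variation", "large_increase"),
        }
        for key, (td, hs, mech) in expected.items():
            row = trans.loc[key]
            assert row["category_total_distance"] == td
            assert row["category_dist_gt_25_2"] == hs
            assert row["category_mechanical_load"] == mech

    def test_readiness_ref_is_earlier_week(self, toy_weeks):
        trans = locoeff.build_transitions(toy_weeks).set_index(["player_id", "week_from"])
        assert trans.loc[("A", 0), "readiness_ref"] == "bad"
        assert trans.loc[("A", 2), "readiness_ref"] == "good"
        trans_to = locoeff.build_transitions(toy_weeks, readiness_ref="to").set_index(
            ["player_id", "week_from"]
        )
        assert trans_to.loc[("A", 0), "readiness_ref"] == "normal"

    def test_lei_variation_signed(self, toy_weeks):
        trans = locoeff.build_transitions(toy_weeks).set_index(["player_id", "week_from"])
        assert trans.loc[("A", 0), "lei_variation"] == pytest.approx(0.8)
        assert trans.loc[("B", 0), "lei_variation"] == pytest.approx(-0.5)

    def test_zero_base_load_dropped_and_counted(self, toy_weeks):
        weeks = toy_weeks.copy()
        weeks.loc[(weeks.player_id == "A") & (weeks.week_index == 1), "dist_gt_25_2"] = 0.0
        trans = locoeff.build_transitions(weeks)
        assert trans.attrs["undefined_pct_changes"]["dist_gt_25_2"] == 1
        row = trans.set_index(["player_id", "week_from"]).loc[("A", 1)]
        assert np.isnan(row["pct_change_dist_gt_25_2"])

    def test_category_counts_sum_to_total(self, toy_weeks):
        trans = locoeff.build_transitions(toy_weeks)
        counts = trans["category_total_distance"].value_counts()
        assert counts.sum() == len(trans)
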