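"""Calendar conventions, session aggregation and the curve filters."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mastphen import (
    CaptureRecord,
    aggregate_sessions,
    assign_cone_year,
    day_offset_from_oct31,
    filter_for_curve,
    first_arrival,
)
from conftest import records


class TestCalendar:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (date(2011, 10, 31), 0),
            (date(2011, 11, 13), 13),   # earliest observed first capture
            (date(2010, 2, 25), 117),   # 30 + 31 + 31 + 25, non-leap February
            (date(2008, 2, 25), 117),   # leap year: 29 Feb exists but is later
            (date(2008, 3, 1), 122),    # ...and shifts March by one day
        ],
    )
    def test_day_offset_from_oct31(self, d, expected):
        assert day_offset_from_oct31(d) == expected

    @pytest.mark.parametrize(
        "d, expected",
        [
            (date(2011, 11, 13), 2011),  # autumn of ripening
            (date(2012, 7, 29), 2011),   # breeding season after the 2011 crop
            (date(2012, 9, 30), 2011),   # season boundary: last day in
            (date(2012, 10, 1), 2012),   # ...and first day out
        ],
    )
    def test_assign_cone_year(self, d, expected):
        assert assign_cone_year(d) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.dates(min_value=date(1990, 1, 1), max_value=date(2040, 12, 31)))
    def test_cone_year_partition_total_and_contiguous(self, d):
        """Every date gets exactly one cone year; the assignment only ever
        steps up by one, at 1 Oct."""
        y = assign_cone_year(d)
        assert y in (d.year, d.year - 1)
        nxt = assign_cone_year(d + pd.Timedelta(days=1))
        assert nxt - y in (0, 1)
        if nxt - y == 1:
            assert (pd.Timestamp(d) + pd.Timedelta(days=1)).month == 10


class TestCaptureRecord:
    def test_fledgling_cannot_be_adult(self):
        with pytest.raises(ValueError):
            CaptureRecord(date(2010, 5, 1), "SISKIN", "A1", 5, fledgling=True)

    def test_mass_must_be_positive(self):
        with pytest.raises(ValueError):
            CaptureRecord(date(2010, 5, 1), "SISKIN", "A1", 4, mass_g=0.0)


class TestAggregateSessions:
    def test_counts_and_ratios_single_session(self):
        df = records(
            [
                ("2012-05-01", "SISKIN", "A1", 4, 0, "F"),
                ("2012-05-01", "SISKIN", "A2", 6, 0, "M"),
                ("2012-05-01", "SISKIN", "A3", 3, 1, "U"),
            ]
        )
        out = aggregate_sessions(df, "SISKIN")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_total"] == 3
        assert row["n_adults"] == 2
        assert row["sex_ratio"] == 0.5
        assert row["fledgling_ratio"] == pytest.approx(1 / 3)
        assert row["cone_year"] == 2011

    def test_empty_input_gives_empty_output(self):
        empty = records([("2012-05-01", "SISKIN")]).iloc[0:0]
        out = aggregate_sessions(empty, "SISKIN")
        assert out.empty

    def test_unsexed_adults_leave_sex_ratio_undefined(self):
        df = records(
            [
                ("2012-05-01", "SISKIN", "A1", 4, 0, "U"),
                ("2012-05-01", "SISKIN", "A2", 4, 0, "U"),
            ]
        )
        out = aggregate_sessions(df, "SISKIN")
        assert out.iloc[0]["n_adults"] == 2
        assert np.isnan(out.iloc[0]["sex_ratio"])

    def test_code_4_adult_but_not_first_year(self):
        df = records(
            [
                ("2012-05-01", "SISKIN", "A1", 4, 0, "M"),
                ("2012-05-01", "SISKIN", "A2", 5, 0, "M"),
                ("2012-05-01", "SISKIN", "A3", 6, 0, "F"),
            ]
        )
        row = aggregate_sessions(df, "SISKIN").iloc[0]
        assert row["n_adults"] == 3
        assert row["n_adult_first_year"] == 1
        assert row["first_year_ratio"] == 0.5  # code 4 out of the aged-adult pool

    def test_conflicting_duplicate_ring_raises(self):
        df = records(
            [
                ("2012-05-01", "SISKIN", "A1", 4, 0, "F"),
                ("2012-05-01", "SISKIN", "A1", 4, 0, "M"),
            ]
        )
        with pytest.raises(ValueError, match="A1"):
            aggregate_sessions(df, "SISKIN")

    def test_other_species_do_not_leak_into_counts(self):
        df = records(
            [
                ("2012-05-01", "SISKIN", "A1", 4, 0, "F"),
                ("2012-05-01", "CHAFFINCH", "B1", 4, 0, "M"),
            ]
        )
        out = aggregate_sessions(df, "SISKIN")
        assert out.iloc[0]["n_total"] == 1

    def test_conservation_totals_match_record_count(self, default_study):
        """Summing session totals recovers the per-species record count."""
        caps = default_study.captures
        out = aggregate_sessions(caps, "SISKIN")
        assert out["n_total"].sum() == (caps["species"] == "SISKIN").sum()
        assert (out["n_adult_female"] + out["n_adult_male"] <= out["n_adults"]).all()
        ratios = out[["sex_ratio", "fledgling_ratio", "first_year_ratio"]]
        assert ((ratios >= 0) & (ratios <= 1) | ratios.isna()).all().all()


class TestFilterForCurve:
    def _sessions(self):
        return pd.DataFrame(
            {
                "day_of_year": [100, 100, 225, 150],
                "n_adult_female": [10, 7, 30, 8],
                "n_adult_male": [5, 7, 30, 6],
                "n_aged": [20, 14, 80, 15],
                "session_date": pd.to_datetime(
                    ["2012-04-09", "2013-04-10", "2012-08-12", "2012-05-29"]
                ),
            }
        )

    def test_day_and_min_birds_boundaries(self):
        s = self._sessions()
        kept = filter_for_curve(s, "sex_ratio")
        # row 0: 15 sexed adults -> kept; rows 1, 3: 14 -> dropped; row 2: late
        assert list(kept.index) == [0]
        kept_f = filter_for_curve(s, "fledgling_ratio")
        # aged birds: rows 0 (20) and 3 (15) pass, row 1 (14) does not
        assert list(kept_f.index) == [0, 3]

    def test_idempotent_and_order_independent(self):
        s = self._sessions()
        once = filter_for_curve(s, "sex_ratio")
        twice = filter_for_curve(once, "sex_ratio")
        pd.testing.assert_frame_equal(once, twice)
        shuffled = filter_for_curve(s.iloc[::-1], "sex_ratio").sort_index()
        pd.testing.assert_frame_equal(once, shuffled)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            filter_for_curve(self._sessions(), "mass_ratio")


class TestFirstArrival:
    def test_first_session_with_adults(self):
        s = pd.DataFrame(
            {
                "session_date": pd.to_datetime(
                    ["2011-11-05", "2011-11-10", "2011-11-13", "2011-11-20"]
                ),
                "n_adults": [0, 0, 3, 5],
                "oct31_offset": [5, 10, 13, 20],
            }
        )
        arr = first_arrival(s)
        assert arr.defined and arr.oct31_offset == 13

    def test_all_zero_season_is_flagged_not_raised(self):
        s = pd.DataFrame(
            {
                "session_date": pd.to_datetime(["2011-11-05"]),
                "n_adults": [0],
                "oct31_offset": [5],
            }
        )
        assert not first_arrival(s).defined
        assert not first_arrival(s.iloc[0:0]).defined

    def test_detection_lag_bounded_by_session_gap(self):
        """With weekly sessions and a known true arrival day, the detected
        offset can only trail the truth by at most one gap (plus the odd
        zero-catch session right after arrival)."""
        from mastphen import aggregate_sessions, simulate_study
        from mastphen.simulate import SimulationConfig

        cfg = SimulationConfig(n_seasons=4, arrival_sd=0.0, nb_dispersion=50.0)
        study = simulate_study(cfg, seed=7)
        sessions = aggregate_sessions(study.captures, "SISKIN")
        truth = study.truth["seasons"].set_index("cone_year")["arrival_offset"]
        max_gap = cfg.mean_gap_days + cfg.gap_jitter_days
        for year, grp in sessions.groupby("cone_year"):
            arr = first_arrival(grp)
            assert arr.defined
            assert truth[year] <= arr.oct31_offset <= truth[year] + 2 * max_gap
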