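from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import at, rec
from _oracles import oracle_sessionize, random_stream
from portaltypes.sessionize import (
    build_raw_sessions,
    merge_adjacent,
    page_view_lengths,
    sessionize_cohort,
)


class TestBuildRawSessions:
    def test_login_click_logout_is_one_logout_session(self):
        sessions = build_raw_sessions(
            [rec(0, "login"), rec(5, "click", "labresults"), rec(10, "logout")]
        )
        (s,) = sessions
        assert (s.start, s.end, s.ended_by) == (at(0), at(10), "logout")
        assert s.length_mins == 10
        assert s.n_clicks == 1

    def test_idle_tail_is_excluded_from_timed_out_session(self):
        # inactivity beyond 20 min ends the session at the last activity
        sessions = build_raw_sessions(
            [rec(0, "login"), rec(5, "click", "labresults"), rec(60, "login")]
        )
        assert len(sessions) == 2
        assert sessions[0].end == at(5)
        assert sessions[0].ended_by == "timeout"
        assert sessions[0].length_mins == 5
        assert sessions[1].start == at(60)

    def test_gap_of_exactly_timeout_does_not_split(self):
        sessions = build_raw_sessions(
            [rec(0, "login"), rec(20, "click", "messaging")], timeout_mins=20
        )
        assert len(sessions) == 1

    def test_gap_just_over_timeout_splits(self):
        sessions = build_raw_sessions(
            [rec(0, "login"), rec(20.5, "click", "messaging")], timeout_mins=20
        )
        assert len(sessions) == 2

    def test_orphan_click_opens_implicit_session(self):
        sessions = build_raw_sessions([rec(0, "click", "messaging")])
        (s,) = sessions
        assert s.start == at(0) and s.n_clicks == 1

    def test_stray_logout_is_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            sessions = build_raw_sessions([rec(0, "logout"), rec(5, "login")])
        assert len(sessions) == 1
        assert "no open session" in caplog.text

    def test_empty_records_give_empty_sessions(self):
        assert build_raw_sessions([]) == []


class TestMergeAdjacent:
    @pytest.mark.parametrize(
        "gap,expected_n",
        [(2.0, 1), (3.0, 1), (3.5, 2)],  # merge boundary is inclusive at 3 min
    )
    def test_three_minute_merge_boundary(self, gap, expected_n):
        raw = build_raw_sessions(
            [
                rec(0, "login"),
                rec(5, "click", "labresults"),
                rec(10, "logout"),
                rec(10 + gap, "login"),
                rec(12 + gap, "click", "messaging"),
                rec(13 + gap, "logout"),
            ]
        )
        merged = merge_adjacent(raw, gap_mins=3)
        assert len(merged) == expected_n
        if expected_n == 1:
            s = merged[0]
            assert s.n_merged == 2
            assert s.start == at(0) and s.end == at(13 + gap)
            # gap time counts: the merged pair is one activity instance
            assert s.length_mins == pytest.approx(13 + gap)
            assert [fn for _, fn in s.clicks] == ["labresults", "messaging"]

    def test_merge_is_transitive(self):
        raw = build_raw_sessions(
            [
                rec(0, "login"), rec(1, "logout"),
                rec(3, "login"), rec(4, "logout"),
                rec(6, "login"), rec(7, "logout"),
            ]
        )
        merged = merge_adjacent(raw)
        assert len(merged) == 1 and merged[0].n_merged == 3

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            raw = build_raw_sessions(random_stream(rng))
            once = merge_adjacent(raw)
            twice = merge_adjacent(once)
            assert [(s.start, s.end, s.n_merged) for s in once] == [
                (s.start, s.end, s.n_merged) for s in twice
            ]

    def test_overlapping_sessions_violate_contract(self):
        a = build_raw_sessions([rec(0, "login"), rec(10, "logout")])
        b = build_raw_sessions([rec(5, "login"), rec(8, "logout")])
        with pytest.raises(ValueError, match="overlapping"):
            merge_adjacent(a + b)


class TestPageViewLengths:
    def test_views_run_click_to_click_and_to_logout(self):
        (s,) = merge_adjacent(
            build_raw_sessions(
                [
                    rec(0, "login"),
                    rec(0, "click", "labresults"),
                    rec(2, "click", "labtests"),
                    rec(5, "logout"),
                ]
            )
        )
        assert page_view_lengths(s) == [2.0, 3.0]

    def test_final_view_omitted_after_timeout(self):
        (s,) = build_raw_sessions([rec(0, "login"), rec(1, "click", "messaging")])
        assert s.ended_by == "timeout"
        assert page_view_lengths(s) == []

    def test_no_clicks_no_views(self):
        (s,) = build_raw_sessions([rec(0, "login"), rec(1, "logout")])
        assert page_view_lengths(s) == []


class TestCohort:
    WINDOW = (datetime(2006, 1, 1), datetime(2007, 1, 1))

    def test_single_merged_session_patient_is_non_user(self):
        cohort = sessionize_cohort(
            [rec(0, "login"), rec(5, "logout")], self.WINDOW
        )
        assert cohort["p1"].user_class == "non_user"

    def test_two_session_patient_is_active(self):
        cohort = sessionize_cohort(
            [rec(0, "login"), rec(5, "logout"), rec(600, "login"), rec(610, "logout")],
            self.WINDOW,
        )
        assert cohort["p1"].user_class == "active"

    def test_re_login_within_merge_window_stays_one_session_hence_non_user(self):
        cohort = sessionize_cohort(
            [rec(0, "login"), rec(5, "logout"), rec(7, "login"), rec(9, "logout")],
            self.WINDOW,
        )
        assert cohort["p1"].n_sessions == 1
        assert cohort["p1"].user_class == "non_user"

    def test_empty_cohort(self):
        assert sessionize_cohort([], self.WINDOW) == {}

    def test_window_is_half_open(self):
        start = datetime(2006, 1, 1)
        end = datetime(2006, 2, 1)
        records = [
            rec(0, "login"),  # conftest T0 = 2006-03-10, outside
        ]
        from portaltypes.logio import LogRecord

        records = [
            LogRecord("p1", start, "login"),
            LogRecord("p1", end, "login"),  # at end: excluded
        ]
        cohort = sessionize_cohort(records, (start, end))
        assert cohort["p1"].n_sessions == 1

    def test_click_count_is_conserved(self, small_cohort, small_sessions):
        from portaltypes.synthetic_data import DEFAULT_WINDOW

        w0, w1 = DEFAULT_WINDOW
        n_clicks_in_window = sum(
            1 for r in small_cohort.records if r.event == "click" and w0 <= r.timestamp < w1
        )
        n_assigned = sum(
            s.n_clicks for ps in small_sessions.values() for s in ps.sessions
        )
        assert n_assigned == n_clicks_in_window


@st.composite
def event_streams(draw):
    from portaltypes.logio import FUNCTION_CODES, LogRecord

    n = draw(st.integers(1, 15))
    t = datetime(2006, 5, 1, 8, 0)
    records = []
    for _ in range(n):
        kind = draw(st.sampled_from(["login", "click", "click", "logout"]))
        fn = draw(st.sampled_from(FUNCTION_CODES)) if kind == "click" else None
        records.append(LogRecord("p1", t, kind, fn))
        t += __import__("datetime").timedelta(
            minutes=draw(st.floats(0.0, 45.0, allow_nan=False))
        )
    return records


class TestStreamProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(event_streams())
    def test_every_click_lands_in_exactly_one_session(self, records):
        sessions = merge_adjacent(build_raw_sessions(records))
        n_clicks = sum(1 for r in records if r.event == "click")
        assert sum(s.n_clicks for s in sessions) == n_clicks
        for s in sessions:
            assert s.length_mins >= 0
            assert s.n_merged >= 1
            for t, _fn in s.clicks:
                assert s.start <= t <= s.end

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(event_streams())
    def test_merging_never_increases_session_count(self, records):
        raw = build_raw_sessions(records)
        assert len(merge_adjacent(raw)) <= len(raw)


class TestOracleEquivalence:
    def _assert_matches(self, records, timeout=20.0, gap=3.0):
        ours = merge_adjacent(build_raw_sessions(records, timeout), gap)
        expected = oracle_sessionize(records, timeout, gap)
        assert len(ours) == len(expected)
        clicks_only = [r for r in records if r.event == "click"]
        for s, e in zip(ours, expected):
            assert (s.start, s.end, s.ended_by, s.n_merged) == (
                e["start"], e["end"], e["ended_by"], e["n_merged"]
            )
            assert [c for c in s.clicks] == [
                (records[i].timestamp, records[i].function) for i in e["clicks"]
            ]
        assert sum(s.n_clicks for s in ours) == len(clicks_only)

    def test_random_streams_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            self._assert_matches(random_stream(rng))

    def test_session_counts_monotone_in_parameters(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            records = random_stream(rng)
            raw_counts = [
                len(build_raw_sessions(records, t)) for t in (5, 10, 20, 40)
            ]
            assert raw_counts == sorted(raw_counts, reverse=True)
            raw = build_raw_sessions(records)
            merged_counts = [len(merge_adjacent(raw, g)) for g in (0.5, 3, 10, 60)]
            assert merged_counts == sorted(merged_counts, reverse=True)
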