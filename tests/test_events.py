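"""Event-log reading, demographics normalization, and sessionization."""

import numpy as np
import pandas as pd
import pytest

import inactigraphy as ig
from inactigraphy.events import EVENT_COLUMNS

HEADER = ",".join(EVENT_COLUMNS)


def write_events(tmp_path, lines, name="events.csv"):
    p = tmp_path / name
    p.write_text("\n".join([HEADER] + lines) + "\n")
    return p


class TestReadEventLog:
    def test_empty_file_with_header(self, tmp_path):
        events = ig.read_event_log(write_events(tmp_path, []))
        assert len(events) == 0
        assert events.attrs["n_malformed"] == 0

    def test_single_row(self, tmp_path):
        events = ig.read_event_log(
            write_events(tmp_path, ["p1,2022-03-01T10:00:00,screen_on,"]))
        assert len(events) == 1
        row = events.iloc[0]
        assert row["participant_id"] == "p1"
        assert row["event_type"] == "screen_on"
        assert row["timestamp"] == pd.Timestamp("2022-03-01 10:00:00")

    def test_unparseable_timestamp_dropped_with_count(self, tmp_path):
        events = ig.read_event_log(write_events(tmp_path, [
            "p1,not-a-date,screen_on,",
            "p1,2022-03-01T10:00:00,screen_on,",
        ]))
        assert len(events) == 1
        assert events.attrs["n_malformed"] == 1

    def test_app_event_without_app_id_dropped(self, tmp_path):
        events = ig.read_event_log(
            write_events(tmp_path, ["p1,2022-03-01T10:00:00,app_start,"]))
        assert len(events) == 0
        assert events.attrs["n_malformed"] == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ig.read_event_log(tmp_path / "nope.csv")

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("participant_id,timestamp,event_type\n")
        with pytest.raises(ValueError, match="app_id"):
            ig.read_event_log(p)

    def test_sorted_by_participant_and_time(self, tmp_path):
        events = ig.read_event_log(write_events(tmp_path, [
            "p2,2022-03-01T09:00:00,screen_on,",
            "p1,2022-03-01T11:00:00,screen_on,",
            "p1,2022-03-01T10:00:00,screen_off,",
        ]))
        assert list(events["participant_id"]) == ["p1", "p1", "p2"]
        assert events["timestamp"].iloc[0] < events["timestamp"].iloc[1]


class TestReadDemographics:
    def write(self, tmp_path, rows):
        p = tmp_path / "demo.csv"
        header = "participant_id,gender,age,highest_degree,employment,use_type"
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    def test_prefer_not_to_answer_becomes_excluded(self, tmp_path):
        profiles = ig.read_demographics(self.write(
            tmp_path, ["p1,Prefer not to answer,27,master,full_time,private_only"]))
        assert profiles["gender"].iloc[0] == "excluded"

    def test_age_binning(self, tmp_path):
        profiles = ig.read_demographics(self.write(tmp_path, [
            "p1,female,27,master,full_time,private_only",
            "p2,male,17,high school,student,both equally",
            "p3,female,35,Bachelor's degree,part-time,mainly private",
            "p4,male,60,doctorate,retired,work only",
        ]))
        assert list(profiles["age_range"]) == ["18-<35", "<18", "35-<60", ">=60"]
        assert list(profiles["highest_degree"]) == [
            "master", "high_school", "bachelor", "doctorate"]
        assert list(profiles["employment"]) == [
            "full_time", "in_education", "part_time", "retired"]

    def test_unknown_tokens_become_excluded(self, tmp_path):
        profiles = ig.read_demographics(self.write(
            tmp_path, ["p1,Other,27,Unknown,astronaut,private_only"]))
        assert profiles["gender"].iloc[0] == "excluded"
        assert profiles["highest_degree"].iloc[0] == "excluded"
        assert profiles["employment"].iloc[0] == "excluded"

    def test_duplicate_id_error(self, tmp_path):
        p = self.write(tmp_path, [
            "p1,female,27,master,full_time,private_only",
            "p1,male,30,master,full_time,private_only",
        ])
        with pytest.raises(ValueError, match="p1"):
            ig.read_demographics(p)


def events_frame(rows, pid="p1"):
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": pd.to_datetime([r[0] for r in rows]),
        "event_type": [r[1] for r in rows],
        "app_id": [r[2] if len(r) > 2 else "" for r in rows],
    })


class TestBuildSessions:
    def test_direct_pairing(self):
        sessions = ig.build_sessions(events_frame([
            ("2022-03-01 10:00", "app_start", "facebook"),
            ("2022-03-01 10:30", "app_end", "facebook"),
        ]))
        assert len(sessions) == 1
        assert sessions["start"].iloc[0] == pd.Timestamp("2022-03-01 10:00")
        assert sessions["end"].iloc[0] == pd.Timestamp("2022-03-01 10:30")

    def test_foreground_switch_preempts(self):
        sessions = ig.build_sessions(events_frame([
            ("2022-03-01 10:00", "app_start", "A"),
            ("2022-03-01 10:20", "app_start", "B"),
            ("2022-03-01 10:40", "app_end", "B"),
        ]))
        assert len(sessions) == 2
        a, b = sessions.iloc[0], sessions.iloc[1]
        assert (a["app_id"], str(a["start"].time()), str(a["end"].time())) == \
            ("A", "10:00:00", "10:20:00")
        assert (b["app_id"], str(b["start"].time()), str(b["end"].time())) == \
            ("B", "10:20:00", "10:40:00")

    def test_orphan_end_warns(self):
        sessions = ig.build_sessions(events_frame([
            ("2022-03-01 10:00", "app_end", "A"),
        ]))
        assert len(sessions) == 0
        assert sessions.attrs["n_warnings"] == 1

    def test_dangling_open_closed_at_last_event(self):
        sessions = ig.build_sessions(events_frame([
            ("2022-03-01 10:00", "app_start", "A"),
            ("2022-03-01 11:00", "screen_off", ""),
            ("2022-03-01 12:00", "app_start", "B"),
        ]))
        # A closed by B's start; B dangling, closed at the last app event, so
        # zero length and discarded.
        assert list(sessions["app_id"]) == ["A"]
        assert sessions["end"].iloc[0] == pd.Timestamp("2022-03-01 12:00")

    def test_session_longer_than_24h_rejected(self):
        sessions = ig.build_sessions(events_frame([
            ("2022-03-01 10:00", "app_start", "A"),
            ("2022-03-02 12:00", "app_end", "A"),
        ]))
        assert len(sessions) == 0
        assert sessions.attrs["n_warnings"] == 1

    def test_shuffle_then_sort_is_stable(self, small_cohort):
        events = small_cohort.events
        shuffled = events.sample(frac=1.0, random_state=3).sort_values(
            ["participant_id", "timestamp", "event_type"],
            kind="stable").reset_index(drop=True)
        a = ig.build_sessions(events)
        b = ig.build_sessions(shuffled)
        pd.testing.assert_frame_equal(a, b)


def test_session_csv_round_trip(tmp_path, small_cohort):
    sessions = small_cohort.sessions
    path = tmp_path / "sessions.csv"
    ig.write_sessions(sessions, path)
    back = ig.read_sessions(path)
    pd.testing.assert_frame_equal(sessions.reset_index(drop=True), back)


def test_screen_intervals_paired():
    intervals = ig.build_screen_intervals(events_frame([
        ("2022-03-01 10:00", "screen_on", ""),
        ("2022-03-01 10:05", "screen_off", ""),
        ("2022-03-01 22:00", "screen_on", ""),
        ("2022-03-01 22:01", "screen_off", ""),
    ]))
    assert len(intervals) == 2
    assert intervals["end"].iloc[0] == pd.Timestamp("2022-03-01 10:05")


def test_usage_event_validation():
    with pytest.raises(ValueError):
        ig.UsageEvent("p1", pd.Timestamp("2022-03-01"), "app_start", "")
    with pytest.raises(ValueError):
        ig.UsageEvent("p1", pd.Timestamp("2022-03-01"), "bogus")


def test_app_session_validation():
    t0 = pd.Timestamp("2022-03-01 10:00")
    with pytest.raises(ValueError):
        ig.AppSession("p1", "a", t0, t0)  # zero length
    with pytest.raises(ValueError):
        ig.AppSession("p1", "a", t0, t0 + pd.Timedelta(hours=25))
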