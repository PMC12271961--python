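"""Smartphone event streams, demographics, and sessionization.

The raw unit of observation is a timestamped device-interaction event
(``screen_on``, ``screen_off``, ``app_start``, ``app_end``) per participant.
Analysis operates on *foreground app sessions* — half-open intervals
``[start, end)`` during which exactly one app is in the foreground — derived
from the event stream by :func:`build_sessions`.

Timestamps are naive local clock times throughout: the nocturnal analysis
window (19:00–06:00) is a wall-clock definition, so no timezone or DST
arithmetic is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("screen_on", "screen_off", "app_start", "app_end")
EVENT_COLUMNS = ("participant_id", "timestamp", "event_type", "app_id")
SESSION_COLUMNS = ("participant_id", "app_id", "start", "end")
DEMOGRAPHICS_COLUMNS = (
    "participant_id", "gender", "age", "highest_degree", "employment", "use_type",
)

#: Maximum credible foreground session; anything longer is treated as a
#: corrupt record (e.g. a lost end event) and rejected.
MAX_SESSION_HOURS = 24.0

EXCLUDED = "excluded"

GENDER_LEVELS = ("female", "male", EXCLUDED)
AGE_LEVELS = ("<18", "18-<35", "35-<60", ">=60", EXCLUDED)
DEGREE_LEVELS = (
    "doctorate", "master", "bachelor", "secondary", "high_school", "none", EXCLUDED,
)
EMPLOYMENT_LEVELS = (
    "in_education", "unemployed", "part_time", "full_time",
    "self_employed", "homemaker", "retired", EXCLUDED,
)
USE_TYPE_LEVELS = (
    "both_equally", "mainly_private", "mainly_work", "private_only", "work_only",
    EXCLUDED,
)

#: Demographic grouping variables in fixed report order.
GROUPING_LEVELS = {
    "gender": GENDER_LEVELS,
    "age_range": AGE_LEVELS,
    "highest_degree": DEGREE_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "use_type": USE_TYPE_LEVELS,
}


@dataclass(frozen=True)
class UsageEvent:
    """A single device-interaction record."""

    participant_id: str
    timestamp: pd.Timestamp
    event_type: str
    app_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.event_type in ("app_start", "app_end") and not self.app_id:
            raise ValueError("app events require a non-empty app_id")


@dataclass(frozen=True)
class AppSession:
    """A foreground app interval, half-open ``[start, end)``."""

    participant_id: str
    app_id: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("session start must precede end")
        if (self.end - self.start) > pd.Timedelta(hours=MAX_SESSION_HOURS):
            raise ValueError("session longer than 24 h rejected as corrupt")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


def _canon(token: object) -> str:
    s = str(token).strip().lower().replace("’", "").replace("'", "")
    for ch in (" ", "-", "/"):
        s = s.replace(ch, "_")
    while "__" in s:
        s = s.replace("__", "_")
    return s


_GENDER_MAP = {"female": "female", "f": "female", "woman": "female",
               "male": "male", "m": "male", "man": "male"}
_DEGREE_MAP = {
    "doctorate": "doctorate", "phd": "doctorate", "doctoral_degree": "doctorate",
    "master": "master", "masters": "master", "masters_degree": "master",
    "bachelor": "bachelor", "bachelors": "bachelor", "bachelors_degree": "bachelor",
    "secondary": "secondary", "secondary_education": "secondary",
    "high_school": "high_school", "high_school_degree": "high_school",
    "high_school_degree_or_equivalent": "high_school",
    "none": "none", "no_formal_qualification": "none",
}
_EMPLOYMENT_MAP = {
    "in_education": "in_education", "student": "in_education",
    "unemployed": "unemployed", "unemployed_or_job_seeking": "unemployed",
    "job_seeking": "unemployed",
    "part_time": "part_time", "full_time": "full_time",
    "self_employed": "self_employed", "homemaker": "homemaker",
    "retired": "retired",
}
_USE_TYPE_MAP = {
    "both_equally": "both_equally", "mainly_private": "mainly_private",
    "mainly_work": "mainly_work", "private_only": "private_only",
    "work_only": "work_only",
}


def _normalize_categorical(series: pd.Series, mapping: dict, levels: tuple) -> pd.Series:
    """Map raw survey tokens onto the analysis enum.

    Any token outside the enum — including "Other", "Prefer not to answer"
    and "Unknown" — becomes ``excluded``, which downstream analyses drop.
    """
    mapped = series.map(lambda v: mapping.get(_canon(v), EXCLUDED))
    return pd.Categorical(mapped, categories=list(levels))


def bin_age(age: pd.Series) -> pd.Series:
    """Bin numeric age into the cohort's four age ranges."""
    numeric = pd.to_numeric(age, errors="coerce")
    out = pd.cut(
        numeric,
        bins=[-np.inf, 18, 35, 60, np.inf],
        right=False,
        labels=["<18", "18-<35", "35-<60", ">=60"],
    )
    out = out.cat.add_categories([EXCLUDED]).fillna(EXCLUDED)
    return pd.Categorical(out, categories=list(AGE_LEVELS))


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read an event-log CSV into a frame sorted by (participant, time).

    Malformed rows (unparseable timestamp, unknown event type, app event
    without an app id) are dropped; the dropped count is logged and stored
    in ``frame.attrs["n_malformed"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"event log {path} missing required columns: {missing}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    ok = ts.notna() & raw["event_type"].isin(EVENT_TYPES)
    is_app = raw["event_type"].isin(("app_start", "app_end"))
    ok &= ~is_app | (raw["app_id"].str.len() > 0)

    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropped %d malformed event rows from %s", n_bad, path)

    events = pd.DataFrame({
        "participant_id": raw.loc[ok, "participant_id"],
        "timestamp": ts[ok],
        "event_type": raw.loc[ok, "event_type"],
        "app_id": raw.loc[ok, "app_id"],
    })
    events = events.sort_values(
        ["participant_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    events.attrs["n_malformed"] = n_bad
    return events


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read and normalize the demographics survey CSV.

    Returns one row per participant with categorical columns ``gender``,
    ``age_range``, ``highest_degree``, ``employment``, ``use_type``.
    Duplicate participant ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"demographics {path} missing required columns: {missing}")

    dupes = raw["participant_id"][raw["participant_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate participant_id: {sorted(set(dupes))}")

    profiles = pd.DataFrame({
        "participant_id": raw["participant_id"],
        "gender": _normalize_categorical(raw["gender"], _GENDER_MAP, GENDER_LEVELS),
        "age_range": bin_age(raw["age"]),
        "highest_degree": _normalize_categorical(
            raw["highest_degree"], _DEGREE_MAP, DEGREE_LEVELS),
        "employment": _normalize_categorical(
            raw["employment"], _EMPLOYMENT_MAP, EMPLOYMENT_LEVELS),
        "use_type": _normalize_categorical(
            raw["use_type"], _USE_TYPE_MAP, USE_TYPE_LEVELS),
    })
    return profiles.reset_index(drop=True)


def _pair_intervals(sub: pd.DataFrame, start_type: str, end_type: str,
                    use_app_id: bool) -> tuple[list, int]:
    """Pair open/close events for one participant into intervals.

    Foreground exclusivity: a new opening event preempts the current open
    interval, closing it at the new event's timestamp.  A close event with
    no matching open interval is ignored with a warning.  A dangling open
    interval is closed at the participant's last event timestamp.
    """
    rows: list = []
    n_warn = 0
    open_app: str | None = None
    open_start: pd.Timestamp | None = None
    pid = sub["participant_id"].iloc[0]
    last_ts = sub["timestamp"].iloc[-1]

    def close(at: pd.Timestamp) -> None:
        nonlocal open_app, open_start, n_warn
        if open_start is None:
            return
        length_h = (at - open_start) / pd.Timedelta(hours=1)
        if length_h > MAX_SESSION_HOURS:
            n_warn += 1
            logger.warning(
                "participant %s: %s session > 24 h rejected as corrupt", pid, open_app)
        elif at > open_start:
            rows.append((pid, open_app, open_start, at))
        open_app = None
        open_start = None

    for ts, etype, app in zip(sub["timestamp"], sub["event_type"], sub["app_id"]):
        if etype == start_type:
            close(ts)
            open_app = app if use_app_id else ""
            open_start = ts
        elif etype == end_type:
            if open_start is not None and (not use_app_id or open_app == app):
                close(ts)
            else:
                n_warn += 1
                logger.warning(
                    "participant %s: %s %r at %s with no open interval",
                    pid, end_type, app, ts)
    close(last_ts)
    return rows, n_warn


def _intervals_from_events(events: pd.DataFrame, start_type: str, end_type: str,
                           use_app_id: bool) -> pd.DataFrame:
    rows: list = []
    n_warn = 0
    for _, sub in events.groupby("participant_id", sort=True, observed=True):
        r, w = _pair_intervals(sub, start_type, end_type, use_app_id)
        rows.extend(r)
        n_warn += w
    out = pd.DataFrame(rows, columns=list(SESSION_COLUMNS))
    if out.empty:
        out = out.astype({"start": "datetime64[ns]", "end": "datetime64[ns]"})
    out = out.sort_values(["participant_id", "start"], kind="stable").reset_index(drop=True)
    out.attrs["n_warnings"] = n_warn
    return out


def build_sessions(events: pd.DataFrame) -> pd.DataFrame:
    """Sessionize app events into foreground intervals.

    Pairs each ``app_start`` with the next ``app_end`` for the same app;
    an ``app_start`` for a different app preempts the open session (only one
    app is foreground at a time).  Zero-length sessions are discarded and
    sessions longer than 24 h are rejected as corrupt.  The warning count is
    stored in ``frame.attrs["n_warnings"]``.
    """
    app_events = events  # screen events pass through untouched; pairing ignores them
    app_only = app_events[app_events["event_type"].isin(("app_start", "app_end"))]
    if app_only.empty:
        empty = pd.DataFrame(columns=list(SESSION_COLUMNS)).astype(
            {"start": "datetime64[ns]", "end": "datetime64[ns]"})
        empty.attrs["n_warnings"] = 0
        return empty
    return _intervals_from_events(app_only, "app_start", "app_end", use_app_id=True)


def build_screen_intervals(events: pd.DataFrame) -> pd.DataFrame:
    """Pair ``screen_on``/``screen_off`` events into screen-on intervals.

    Used as the alternative activity basis for the nocturnal-gap statistic.
    """
    scr = events[events["event_type"].isin(("screen_on", "screen_off"))]
    if scr.empty:
        empty = pd.DataFrame(columns=list(SESSION_COLUMNS)).astype(
            {"start": "datetime64[ns]", "end": "datetime64[ns]"})
        empty.attrs["n_warnings"] = 0
        return empty
    return _intervals_from_events(scr, "screen_on", "screen_off", use_app_id=False)


def write_sessions(sessions: pd.DataFrame, path: str | Path) -> None:
    """Write sessions to CSV with second-resolution ISO timestamps."""
    out = sessions.copy()
    out["start"] = out["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["end"] = out["end"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_sessions(path: str | Path) -> pd.DataFrame:
    """Read a sessions CSV written by :func:`write_sessions`."""
    df = pd.read_csv(path, dtype={"participant_id": str, "app_id": str})
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def events_from_sessions(sessions: pd.DataFrame) -> pd.DataFrame:
    """Expand sessions back into an ``app_start``/``app_end`` event stream."""
    starts = pd.DataFrame({
        "participant_id": sessions["participant_id"],
        "timestamp": sessions["start"],
        "event_type": "app_start",
        "app_id": sessions["app_id"],
    })
    ends = pd.DataFrame({
        "participant_id": sessions["participant_id"],
        "timestamp": sessions["end"],
        "event_type": "app_end",
        "app_id": sessions["app_id"],
    })
    events = pd.concat([starts, ends], ignore_index=True)
    return events.sort_values(
        ["participant_id", "timestamp", "event_type"], kind="stable"
    ).reset_index(drop=True)
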