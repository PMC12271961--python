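"""Nocturnal smartphone inactivity: the sleep-proxy gap statistic.

For each participant-night, the statistic is the longest continuous period
with no smartphone activity inside a clock-defined night window (by default
19:00 on day *d* to 06:00 on day *d+1*, an 11-hour window).  A night whose
longest gap reaches the threshold (default 6 h, inclusive) counts as an
*adequate-sleep* night; participants with no such night across their
recording period form group 1, all others group 2.

Activity is the union of foreground app sessions by default (screen-on
intervals are the alternative basis).  All intervals are half-open, so an
event ending exactly at 19:00 contributes no window coverage.

A night is evaluated only if the participant produced at least one event on
day *d* or day *d+1*: an entirely silent night inside a non-recording
stretch is indistinguishable from the app simply not running, and must not
masquerade as 11 h of inactivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPOCH = pd.Timestamp("1970-01-01")
_HOUR = pd.Timedelta(hours=1)


def parse_clock(value) -> float:
    """Parse a wall-clock time ('19:00', '6', 19.5, datetime.time) to hours."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value)
    if ":" in s:
        h, m = s.split(":", 1)
        return int(h) + int(m) / 60.0
    return float(s)


@dataclass(frozen=True)
class WindowSpec:
    """The nocturnal analysis window and adequate-sleep threshold.

    ``start_clock`` is hours after midnight on the night's own day;
    ``end_clock`` is hours after midnight on the following day.
    """

    start_clock: float = 19.0
    end_clock: float = 6.0
    threshold_hours: float = 6.0

    def __post_init__(self) -> None:
        length = self.window_hours
        if not 0 < length <= 24:
            raise ValueError(f"window length {length} h outside (0, 24]")
        if not 0 <= self.threshold_hours <= length:
            raise ValueError("threshold must lie within the window length")

    @property
    def window_hours(self) -> float:
        return 24.0 - self.start_clock + self.end_clock


def _to_hours(ts: pd.Series) -> np.ndarray:
    """Naive timestamps -> float hours since the epoch."""
    return ts.astype("int64").to_numpy() / 3.6e12


def _longest_gap(starts_h: np.ndarray, ends_h: np.ndarray,
                 w0: float, w1: float) -> float:
    """Longest uncovered run in [w0, w1) given activity intervals in hours."""
    s = np.clip(starts_h, w0, w1)
    e = np.clip(ends_h, w0, w1)
    keep = e > s
    s, e = s[keep], e[keep]
    if s.size == 0:
        return w1 - w0
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    longest = s[0] - w0
    cur_end = e[0]
    for i in range(1, s.size):
        if s[i] > cur_end:
            gap = s[i] - cur_end
            if gap > longest:
                longest = gap
        if e[i] > cur_end:
            cur_end = e[i]
    return max(longest, w1 - cur_end)


def longest_inactivity_gap(
    activity: pd.DataFrame, night_date, window: WindowSpec = WindowSpec()
) -> float:
    """Longest inactivity gap (hours) in the night window of *night_date*.

    *activity* holds the participant's activity intervals (``start``/``end``
    timestamp columns); intervals are clipped to the window, and gaps cut
    off by a window edge count at their truncated length.  No activity in
    the window yields the full window length.
    """
    d0 = (pd.Timestamp(night_date).normalize() - _EPOCH) / pd.Timedelta(days=1)
    w0 = d0 * 24.0 + window.start_clock
    w1 = (d0 + 1) * 24.0 + window.end_clock
    if activity.empty:
        return w1 - w0
    return _longest_gap(_to_hours(activity["start"]), _to_hours(activity["end"]), w0, w1)


def classify_night(gap_hours: float, threshold: float = 6.0) -> bool:
    """True if the night reaches the adequate-sleep threshold (inclusive)."""
    if gap_hours < 0:
        raise ValueError("gap cannot be negative")
    return gap_hours >= threshold


def night_records(
    activity: pd.DataFrame,
    window: WindowSpec = WindowSpec(),
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-participant-night gap statistics.

    *activity* is the interval frame defining phone use (app sessions or
    screen-on intervals).  *events*, if given, determines which days count
    as recorded (a night is evaluated only when day *d* or *d+1* has at
    least one event); otherwise recorded days are inferred from *activity*.

    Returns columns ``participant_id, night_date, longest_gap_hours,
    adequate``.
    """
    obs = events if events is not None else activity
    obs_times: dict[str, np.ndarray] = {}
    if events is not None:
        for pid, sub in obs.groupby("participant_id", observed=True):
            obs_times[pid] = _to_hours(sub["timestamp"])
    else:
        for pid, sub in obs.groupby("participant_id", observed=True):
            obs_times[pid] = np.concatenate(
                [_to_hours(sub["start"]), _to_hours(sub["end"])])

    rows = []
    groups = {pid: sub for pid, sub in activity.groupby("participant_id", observed=True)}
    for pid in sorted(obs_times):
        times = obs_times[pid]
        days = np.unique((times // 24).astype(np.int64))
        candidates = np.unique(np.concatenate([days, days - 1]))
        sub = groups.get(pid)
        if sub is None:
            s_h = e_h = np.empty(0)
        else:
            s_h, e_h = _to_hours(sub["start"]), _to_hours(sub["end"])
        day_set = set(days.tolist())
        for d in candidates.tolist():
            if d not in day_set and (d + 1) not in day_set:
                continue
            w0 = d * 24.0 + window.start_clock
            w1 = (d + 1) * 24.0 + window.end_clock
            gap = _longest_gap(s_h, e_h, w0, w1)
            rows.append((pid, _EPOCH + pd.Timedelta(days=d), gap))
    out = pd.DataFrame(rows, columns=["participant_id", "night_date", "longest_gap_hours"])
    if out.empty:
        out["night_date"] = out["night_date"].astype("datetime64[ns]")
    out["adequate"] = out["longest_gap_hours"] >= window.threshold_hours
    return out


def summarize_participant_nights(
    nights: pd.DataFrame, threshold: float | None = None
) -> pd.DataFrame:
    """Collapse night records to one row per participant.

    ``median_gap_adequate_nights`` is the median over nights reaching the
    threshold only (NaN for group-1 participants, who have none);
    ``prop_adequate`` is the fraction of all recorded nights reaching it;
    ``stratum`` is ``group1`` when no night reaches the threshold, else
    ``group2``.  ``mean_gap_hours`` (over all nights) is the participant-
    level quantity used by the association analyses.
    """
    if nights.empty:
        raise ValueError("no night records to summarize")
    df = nights.copy()
    if threshold is not None:
        df["adequate"] = df["longest_gap_hours"] >= threshold

    g = df.groupby("participant_id", observed=True)
    out = pd.DataFrame({
        "n_nights": g.size(),
        "mean_gap_hours": g["longest_gap_hours"].mean(),
        "prop_adequate": g["adequate"].mean(),
    })
    adequate_median = (
        df[df["adequate"]].groupby("participant_id", observed=True)
        ["longest_gap_hours"].median()
    )
    out["median_gap_adequate_nights"] = adequate_median.reindex(out.index)
    out["stratum"] = np.where(out["prop_adequate"] > 0, "group2", "group1")
    out = out[["n_nights", "mean_gap_hours", "median_gap_adequate_nights",
               "prop_adequate", "stratum"]]
    return out.reset_index()


def cohort_inactivity_table(
    summaries: pd.DataFrame,
    profiles: pd.DataFrame,
    groupings: tuple[str, ...] = (
        "gender", "age_range", "highest_degree", "employment", "use_type"),
) -> pd.DataFrame:
    """Per-demographic-level stratification of nocturnal inactivity.

    For each level: participant count, group-1 count and percentage, and —
    within group 2 — the median (with quartiles) of each participant's
    median adequate-night gap and the median percentage of adequate nights.
    Participants without a demographic profile are excluded with a warning.
    An ``all/all`` row summarizes the whole cohort.
    """
    merged = summaries.merge(profiles, on="participant_id", how="left", indicator=True)
    missing = merged["_merge"] == "left_only"
    if missing.any():
        logger.warning("%d participants lack a demographic profile; excluded",
                       int(missing.sum()))
    merged = merged[~missing].drop(columns="_merge")

    def level_row(grouping: str, level: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        n_g1 = int((sub["stratum"] == "group1").sum())
        g2 = sub[sub["stratum"] == "group2"]
        med = g2["median_gap_adequate_nights"]
        return {
            "grouping": grouping,
            "level": level,
            "n": n,
            "n_group1": n_g1,
            "pct_group1": round(100.0 * n_g1 / n, 1) if n else np.nan,
            "n_group2": len(g2),
            "g2_median_gap_hours": med.median() if len(g2) else np.nan,
            "g2_gap_q1": med.quantile(0.25) if len(g2) else np.nan,
            "g2_gap_q3": med.quantile(0.75) if len(g2) else np.nan,
            "g2_pct_adequate_nights": (
                100.0 * g2["prop_adequate"].median() if len(g2) else np.nan),
        }

    rows = [level_row("all", "all", merged)]
    from .events import GROUPING_LEVELS

    for grouping in groupings:
        for level in GROUPING_LEVELS[grouping]:
            sub = merged[merged[grouping].astype(str) == level]
            if len(sub) == 0:
                continue
            rows.append(level_row(grouping, level, sub))
    return pd.DataFrame(rows)
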