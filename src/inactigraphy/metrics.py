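"""Daily usage metrics: total and per-category durations and frequencies.

Total daily usage is the length of the *interval union* of that day's
foreground sessions, so overlapping or duplicated records can never push a
day above 24 h of use.  Per-category durations are plain sums of session
lengths within the category, so their total may exceed the union.
Sessions crossing midnight are split at midnight before aggregating
durations; session counts are attributed to the day a session started.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxonomy import CATEGORIES, CategoryMapping

_HOUR = pd.Timedelta(hours=1)

HOUR_COLS = [f"hours_{c}" for c in CATEGORIES]
COUNT_COLS = [f"count_{c}" for c in CATEGORIES]


@dataclass(frozen=True)
class DailyUsage:
    """Usage metrics for one participant-day."""

    participant_id: str
    date: pd.Timestamp
    total_hours: float
    session_count: int
    per_category_hours: dict[str, float]
    per_category_count: dict[str, int]


def interval_union_hours(starts, ends) -> float:
    """Length in hours of the union of half-open intervals ``[start, end)``."""
    starts = np.asarray(pd.to_datetime(pd.Series(starts)).astype("int64"), dtype=np.int64)
    ends = np.asarray(pd.to_datetime(pd.Series(ends)).astype("int64"), dtype=np.int64)
    if starts.size == 0:
        return 0.0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total / 3.6e12  # ns -> h


def split_at_midnight(sessions: pd.DataFrame) -> pd.DataFrame:
    """Split sessions crossing midnight into per-day pieces.

    Returns a frame with the same columns plus ``date`` (the calendar day of
    each piece) and ``piece_hours``; the original session index is preserved
    in ``session_index`` so counts can still be taken per original session.
    """
    df = sessions.reset_index(drop=True).copy()
    df["session_index"] = df.index
    pieces = []
    start, end = df["start"], df["end"]
    day = start.dt.normalize()
    while True:
        next_midnight = day + pd.Timedelta(days=1)
        piece_end = np.minimum(end, next_midnight)
        piece = df.copy()
        piece["date"] = day
        piece["piece_hours"] = (piece_end - start) / _HOUR
        pieces.append(piece[piece["piece_hours"] > 0].assign(
            start=start, end=piece_end))
        crosses = end > next_midnight
        if not crosses.any():
            break
        df = df[crosses].copy()
        start = next_midnight[crosses]
        end = df["end"]
        day = start.dt.normalize()
        df["start"] = start
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(
        ["participant_id", "start"], kind="stable").reset_index(drop=True)


def daily_usage_table(sessions: pd.DataFrame, mapping: CategoryMapping) -> pd.DataFrame:
    """One row of usage metrics per participant-day with any recorded session.

    Days without sessions do not appear: an absent day is non-recording, not
    zero use, because recording periods varied between participants.
    """
    if sessions.empty:
        cols = (["participant_id", "date", "total_hours", "session_count"]
                + HOUR_COLS + COUNT_COLS)
        return pd.DataFrame(columns=cols)

    pieces = split_at_midnight(sessions)
    pieces["category"] = mapping.lookup_series(pieces["app_id"])

    key = ["participant_id", "date"]
    # Vectorized union length per day: with pieces sorted by start, a piece
    # contributes end minus the running coverage high-water mark.
    pieces = pieces.sort_values(key + ["start"], kind="stable")
    start_ns = pieces["start"].astype("int64")
    end_ns = pieces["end"].astype("int64")
    grouped_end = end_ns.groupby(
        [pieces["participant_id"], pieces["date"]], observed=True)
    high_water = grouped_end.cummax().groupby(
        [pieces["participant_id"], pieces["date"]], observed=True).shift(1)
    contrib = (end_ns - np.maximum(start_ns, high_water.fillna(start_ns))).clip(lower=0)
    total = (
        contrib.groupby([pieces["participant_id"], pieces["date"]], observed=True)
        .sum()
        .div(3.6e12)
        .rename("total_hours")
    )
    total.index.names = key
    cat_hours = (
        pieces.pivot_table(index=key, columns="category", values="piece_hours",
                           aggfunc="sum", fill_value=0.0, observed=True)
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
    )
    cat_hours.columns = HOUR_COLS

    # Counts are per original session, attributed to its start day.
    orig = sessions.reset_index(drop=True).copy()
    orig["date"] = orig["start"].dt.normalize()
    orig["category"] = mapping.lookup_series(orig["app_id"])
    counts = orig.groupby(key, observed=True).size().rename("session_count")
    cat_counts = (
        orig.pivot_table(index=key, columns="category", values="app_id",
                         aggfunc="count", fill_value=0, observed=True)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    cat_counts.columns = COUNT_COLS

    out = pd.concat([total, cat_hours], axis=1).join(counts).join(cat_counts)
    out["session_count"] = out["session_count"].fillna(0).astype(int)
    out[COUNT_COLS] = out[COUNT_COLS].fillna(0).astype(int)
    return out.reset_index().sort_values(key).reset_index(drop=True)


def compute_daily_usage(
    sessions: pd.DataFrame,
    mapping: CategoryMapping,
    participant_id: str,
    date,
) -> DailyUsage:
    """Usage metrics for a single participant-day (no sessions → all zero)."""
    date = pd.Timestamp(date).normalize()
    sub = sessions[sessions["participant_id"] == participant_id]
    table = daily_usage_table(sub, mapping)
    row = table[table["date"] == date]
    if row.empty:
        return DailyUsage(participant_id, date, 0.0, 0,
                          {c: 0.0 for c in CATEGORIES}, {c: 0 for c in CATEGORIES})
    r = row.iloc[0]
    return DailyUsage(
        participant_id,
        date,
        float(r["total_hours"]),
        int(r["session_count"]),
        {c: float(r[f"hours_{c}"]) for c in CATEGORIES},
        {c: int(r[f"count_{c}"]) for c in CATEGORIES},
    )


def compute_category_shares(daily: pd.DataFrame, basis: str = "duration") -> pd.Series:
    """Category shares of total app use, on a duration or frequency basis.

    ``share_k = sum(category_k) / sum(all categories)``; shares sum to one.
    """
    if basis not in ("duration", "frequency"):
        raise ValueError(f"basis must be 'duration' or 'frequency', got {basis!r}")
    cols = HOUR_COLS if basis == "duration" else COUNT_COLS
    sums = daily[cols].sum().astype(float)
    total = sums.sum()
    if total <= 0:
        raise ValueError("cannot compute shares from all-zero usage")
    shares = sums / total
    shares.index = list(CATEGORIES)
    return shares


def participant_usage_summary(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean and median of daily usage metrics.

    Averages run over *recorded* days only.  Both mean and median are
    reported for the total and for each category.
    """
    if daily.empty:
        raise ValueError("no recorded days to summarize")
    g = daily.groupby("participant_id", observed=True)
    out = pd.DataFrame({
        "n_days": g.size(),
        "mean_total_hours": g["total_hours"].mean(),
        "median_total_hours": g["total_hours"].median(),
        "mean_session_count": g["session_count"].mean(),
    })
    for c, col in zip(CATEGORIES, HOUR_COLS):
        out[f"mean_hours_{c}"] = g[col].mean()
        out[f"median_hours_{c}"] = g[col].median()
    return out.reset_index()
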