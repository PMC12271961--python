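"""End-to-end analysis pipeline and report tables.

Three phases: (1) cohort description and daily usage metrics, (2) group
comparisons of usage and nocturnal-inactivity indicators across demographic
strata, (3) per-subgroup associations between usage and the night gap.
Every table is written as CSV with fixed row order and fixed float
precision so repeated runs are byte-identical; every exclusion is counted
in a plain-text run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association as assoc
from . import comparison as comp
from .events import (GROUPING_LEVELS, build_screen_intervals, build_sessions,
                     read_demographics, read_event_log)
from .metrics import daily_usage_table, compute_category_shares, participant_usage_summary
from .nights import (WindowSpec, cohort_inactivity_table, night_records,
                     summarize_participant_nights)
from .taxonomy import CategoryMapping, default_mapping, load_mapping

GROUPINGS = ("gender", "age_range", "highest_degree", "employment", "use_type")

#: Participant-level variables entering the comparison battery.
COMPARISON_VARIABLES = (
    "mean_total_hours",
    "mean_hours_A", "mean_hours_B", "mean_hours_C", "mean_hours_D", "mean_hours_E",
    "mean_gap_hours",
    "prop_adequate",
)


class StageError(RuntimeError):
    """A pipeline phase failed; the message names the stage."""


@dataclass
class PipelineConfig:
    events_path: str | Path
    demographics_path: str | Path
    out_dir: str | Path
    mapping_path: str | Path | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    activity_basis: str = "app"          # "app" | "screen"
    correlation_method: str = "pearson"  # "pearson" | "spearman"
    adjustment: str = "holm"             # Dunn multiplicity adjustment
    seed: int = 0                        # reserved for resampling options

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a pipeline configuration from a YAML file.

        Window settings live under a ``window`` key (``start_clock``,
        ``end_clock``, ``threshold_hours``); everything else maps directly
        onto the dataclass fields.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        window_raw = raw.pop("window", None)
        if window_raw is not None:
            from .nights import parse_clock

            raw["window"] = WindowSpec(
                start_clock=parse_clock(window_raw.get("start_clock", 19.0)),
                end_clock=parse_clock(window_raw.get("end_clock", 6.0)),
                threshold_hours=float(window_raw.get("threshold_hours", 6.0)),
            )
        unknown = set(raw) - {f.name for f in
                              cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def cohort_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Cohort composition: count and percentage per demographic level.

    All enum levels appear in fixed order (zero-count levels included) and
    survey non-response (``excluded``) is reported as its own row.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles")
    n_total = len(profiles)
    rows = []
    for grouping in GROUPINGS:
        counts = profiles[grouping].astype(str).value_counts()
        for level in GROUPING_LEVELS[grouping]:
            n = int(counts.get(level, 0))
            rows.append({
                "grouping": grouping,
                "level": level,
                "n": n,
                "pct": round(100.0 * n / n_total, 1),
            })
    return pd.DataFrame(rows)


def _comparison_tables(values: pd.DataFrame, profiles: pd.DataFrame,
                       adjustment: str, log: list[str]):
    summary_rows = []
    pairwise_rows = []
    for variable in COMPARISON_VARIABLES:
        if variable not in values.columns:
            continue
        for grouping in GROUPINGS:
            try:
                res = comp.compare_groups(
                    values[["participant_id", variable]], profiles, grouping,
                    variable, adjustment=adjustment)
            except ValueError as exc:
                log.append(f"comparison skipped: {variable} by {grouping}: {exc}")
                continue
            for _, row in res.summary.iterrows():
                summary_rows.append({
                    "variable": variable, "grouping": grouping,
                    "level": row["level"], "n": int(row["n"]),
                    "median": row["median"], "q1": row["q1"], "q3": row["q3"],
                    "shapiro_p": row["shapiro_p"],
                    "levene_W": res.levene_W, "levene_p": res.levene_p,
                    "H": res.H, "df": res.df, "p_value": res.p_value,
                })
            for _, row in res.pairwise.iterrows():
                pairwise_rows.append({
                    "variable": variable, "grouping": grouping,
                    "group_i": row["group_i"], "group_j": row["group_j"],
                    "z": row["z"], "p_raw": row["p_raw"],
                    "p_adjusted": row["p_adjusted"],
                })
    return pd.DataFrame(summary_rows), pd.DataFrame(pairwise_rows)


def _write(df: pd.DataFrame, path: Path, date_cols: tuple[str, ...] = ()) -> None:
    out = df.copy()
    for col in date_cols:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.4f")


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all three phases and write the report bundle to ``out_dir``.

    Returns the report tables keyed by file stem.  A failure in any phase
    raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    # ---- phase 1: cohort description and usage metrics -------------------
    try:
        events = read_event_log(config.events_path)
        if events.empty:
            raise ValueError("event log contains no usable events")
        profiles = read_demographics(config.demographics_path)
        mapping: CategoryMapping = (
            load_mapping(config.mapping_path) if config.mapping_path
            else default_mapping())
        log.append(f"events read: {len(events)}")
        log.append(f"events dropped as malformed: {events.attrs.get('n_malformed', 0)}")
        log.append(f"profiles read: {len(profiles)}")

        sessions = build_sessions(events)
        log.append(f"sessions built: {len(sessions)}")
        log.append(f"sessionization warnings: {sessions.attrs.get('n_warnings', 0)}")

        daily = daily_usage_table(sessions, mapping)
        usage_summary = participant_usage_summary(daily)
        tables["cohort_table"] = cohort_table(profiles)
        tables["daily_usage"] = daily
        tables["participant_usage"] = usage_summary
        shares = []
        for basis in ("duration", "frequency"):
            s = compute_category_shares(daily, basis=basis)
            for cat, share in s.items():
                shares.append({"basis": basis, "category": cat, "share": share})
        tables["category_shares"] = pd.DataFrame(shares)
    except Exception as exc:
        raise StageError(f"phase 1 (cohort and usage metrics) failed: {exc}") from exc

    # ---- phase 2: nocturnal inactivity and group comparisons -------------
    try:
        if config.activity_basis == "app":
            activity = sessions
        elif config.activity_basis == "screen":
            activity = build_screen_intervals(events)
        else:
            raise ValueError(f"unknown activity basis {config.activity_basis!r}")
        nights = night_records(activity, window=config.window, events=events)
        night_summary = summarize_participant_nights(nights)
        log.append(f"nights evaluated: {len(nights)}")
        n_no_profile = len(
            set(night_summary["participant_id"]) - set(profiles["participant_id"]))
        log.append(f"participants without profile (excluded from tables): {n_no_profile}")

        tables["night_records"] = nights
        tables["participant_nights"] = night_summary
        tables["inactivity_table"] = cohort_inactivity_table(night_summary, profiles)

        values = usage_summary.merge(
            night_summary[["participant_id", "mean_gap_hours", "prop_adequate"]],
            on="participant_id", how="inner")
        summary_tab, pairwise_tab = _comparison_tables(
            values, profiles, config.adjustment, log)
        tables["group_comparisons"] = summary_tab
        tables["dunn_pairwise"] = pairwise_tab
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"phase 2 (nights and comparisons) failed: {exc}") from exc

    # ---- phase 3: associations -------------------------------------------
    try:
        assoc_frames = []
        for grouping in GROUPINGS:
            res = assoc.subgroup_associations(
                usage_summary, night_summary, profiles, grouping,
                method=config.correlation_method)
            if len(res):
                assoc_frames.append(res)
        tables["associations"] = (
            pd.concat(assoc_frames, ignore_index=True) if assoc_frames
            else pd.DataFrame())
        log.append(f"association rows: {len(tables['associations'])}")
    except Exception as exc:
        raise StageError(f"phase 3 (associations) failed: {exc}") from exc

    _write(tables["cohort_table"], out_dir / "cohort_table.csv")
    _write(tables["daily_usage"], out_dir / "daily_usage.csv", date_cols=("date",))
    _write(tables["participant_usage"], out_dir / "participant_usage.csv")
    _write(tables["category_shares"], out_dir / "category_shares.csv")
    _write(tables["night_records"], out_dir / "night_records.csv",
           date_cols=("night_date",))
    _write(tables["participant_nights"], out_dir / "participant_nights.csv")
    _write(tables["inactivity_table"], out_dir / "inactivity_table.csv")
    _write(tables["group_comparisons"], out_dir / "group_comparisons.csv")
    _write(tables["dunn_pairwise"], out_dir / "dunn_pairwise.csv")
    _write(tables["associations"], out_dir / "associations.csv")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return tables
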