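"""Synthetic smartphone-usage cohorts with known ground truth.

The generator emulates the structure of a passively sensed cohort: each
participant contributes a multi-day stream of foreground app sessions drawn
from a daytime renewal process, a nightly sleep window (truncated-normal
onset and duration), an anchoring "phone in bed" session ending at sleep
onset plus a brief wake-up check, occasional nocturnal phone checks, and a
demographic profile drawn from a realistic composition.  Ground truth
(true sleep onset/wake per night, true usage volume per participant) is
returned alongside, so every downstream estimate can be validated against
what was planted.

Effect switches plant known signals for recovery tests: a male sleep-onset
delay (shifting the male nocturnal-gap distribution down), a participant-
level latent correlation between usage volume and the night gap, a within-
night coupling where excess evening use delays that night's onset, and a
gender-dependent app-category mixture.

Each participant owns one pseudo-random stream derived from (master seed,
participant index), so growing the cohort never reshuffles existing
participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nights import WindowSpec

_EPOCH = pd.Timestamp("1970-01-01")

#: App pools per category, matching the bundled default taxonomy.
APP_POOLS = {
    "A": ["google", "firefox", "duolingo", "wikipedia", "news"],
    "B": ["youtube", "netflix", "spotify", "candycrush", "tiktok"],
    "C": ["clock", "calculator", "calendar", "email", "weather"],
    "D": ["facebook", "whatsapp", "instagram", "telegram", "signal"],
    "E": ["paypal", "amazon", "ebay", "banking", "zalando"],
    "unknown": ["com.example.misc", "com.vendor.widget"],
}

#: Demographic composition defaults: category probabilities mirroring a
#: large German convenience cohort (mostly young, female-majority, many
#: students).  "excluded" stands for survey non-response.
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "gender": {"female": 724, "male": 350},
    "age_range": {"<18": 8, "18-<35": 895, "35-<60": 161, ">=60": 10},
    "highest_degree": {
        "doctorate": 11, "master": 116, "bachelor": 189, "secondary": 96,
        "high_school": 637, "none": 10, "excluded": 15,
    },
    "employment": {
        "in_education": 535, "unemployed": 20, "part_time": 149, "full_time": 267,
        "self_employed": 41, "homemaker": 14, "retired": 17, "excluded": 31,
    },
    "use_type": {
        "both_equally": 139, "mainly_private": 390, "mainly_work": 14,
        "private_only": 524, "work_only": 7,
    },
}

_AGE_RANGES = {"<18": (14, 17), "18-<35": (18, 34), "35-<60": (35, 59), ">=60": (60, 75)}

#: Baseline session-category mixture, social-media and entertainment heavy.
DEFAULT_CATEGORY_PROBS = {
    "A": 0.15, "B": 0.22, "C": 0.16, "D": 0.36, "E": 0.06, "unknown": 0.05,
}


@dataclass(frozen=True)
class SleepModel:
    """Truncated-normal sleep windows, split into stable between-participant
    means and nightly noise.  Clock hours count from midnight of the night's
    own day, so values above 24 mean falling asleep after midnight."""

    onset_mean_clock: float = 23.25
    onset_between_sd: float = 0.75
    onset_within_sd: float = 0.5
    onset_bounds: tuple[float, float] = (20.5, 26.5)
    duration_mean: float = 7.5
    duration_between_sd: float = 0.75
    duration_within_sd: float = 0.5
    duration_bounds: tuple[float, float] = (3.5, 10.5)
    #: Correlation between a participant's earliness of sleep onset and
    #: their sleep duration (earlier sleepers sleep longer).
    trait_coupling: float = 0.6


@dataclass(frozen=True)
class UsageModel:
    """Daytime sessions: exponential inter-arrival renewal process with
    log-normal session lengths (median ≈3 min), a phone-in-bed session
    ending at sleep onset, and a brief check shortly after waking."""

    session_rate_per_hour: float = 3.2
    rate_rel_sd: float = 0.35
    session_len_log_mean: float = float(np.log(0.05))  # hours; median 3 min
    session_len_log_sd: float = 1.0
    bedtime_use_prob: float = 0.9
    wake_check_prob: float = 0.9
    wake_check_delay_max_min: float = 5.0
    first_day_start_clock: float = 7.5
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))


@dataclass(frozen=True)
class NightCheckModel:
    """Brief mid-sleep phone checks (the only activity allowed to overlap
    the true sleep interval)."""

    prob_per_night: float = 0.15
    length_min_minutes: float = 1.0
    length_max_minutes: float = 5.0


@dataclass(frozen=True)
class Effects:
    """Planted signals; all zero/off means the null scenario."""

    male_onset_shift_hours: float = 0.0
    usage_gap_rho: float = 0.0
    evening_coupling: float = 0.0
    gendered_mixture: bool = False


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 100
    n_days: int = 14
    seed: int = 0
    start_date: str = "2022-03-01"
    composition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPOSITION.items()})
    sleep: SleepModel = field(default_factory=SleepModel)
    usage: UsageModel = field(default_factory=UsageModel)
    night_checks: NightCheckModel = field(default_factory=NightCheckModel)
    effects: Effects = field(default_factory=Effects)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("n_participants and n_days must be >= 1")
        for name, probs in self.composition.items():
            total = sum(probs.values())
            if total <= 0 or any(p < 0 for p in probs.values()):
                raise ValueError(f"invalid composition for {name}")


@dataclass
class SimResult:
    """Everything one simulated cohort produces."""

    config: SimConfig
    demographics: pd.DataFrame       # raw survey-style CSV rows
    profiles: pd.DataFrame           # normalized categorical profiles
    sessions: pd.DataFrame           # participant_id, app_id, start, end
    events: pd.DataFrame             # app_start/app_end stream
    night_truth: pd.DataFrame        # true onset/wake and in-window sleep per night
    participant_truth: pd.DataFrame  # latent usage volume and sleep means


def scenario(name: str, n_participants: int | None = None,
             n_days: int | None = None, seed: int | None = None) -> SimConfig:
    """Named study presets.

    ``null`` — every stratum shares one distribution (all effects off).
    ``gender_gap`` — male sleep onset delayed 0.5 h, shifting the male
    nightly gap distribution down by 0.5 h.
    ``usage_sleep_coupling`` — participant-level usage volume and night gap
    drawn with latent correlation −0.6.
    ``taxonomy_mixture`` — app-category mixture differs by gender.
    """
    effects = {
        "null": Effects(),
        "gender_gap": Effects(male_onset_shift_hours=0.5),
        "usage_sleep_coupling": Effects(usage_gap_rho=-0.6),
        "taxonomy_mixture": Effects(gendered_mixture=True),
    }
    if name not in effects:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(effects)}")
    cfg = SimConfig(effects=effects[name])
    overrides = {}
    if n_participants is not None:
        overrides["n_participants"] = n_participants
    if n_days is not None:
        overrides["n_days"] = n_days
    if seed is not None:
        overrides["seed"] = seed
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _draw_profile(rng: np.random.Generator, composition) -> dict[str, str]:
    out = {}
    for var, probs in composition.items():
        levels = list(probs)
        p = np.array([probs[lv] for lv in levels], dtype=float)
        out[var] = levels[rng.choice(len(levels), p=p / p.sum())]
    return out


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _mixture_for(profile: dict[str, str], usage: UsageModel, effects: Effects):
    probs = dict(usage.category_probs)
    if effects.gendered_mixture:
        # Female usage skews social/monetary, male leisure-entertainment.
        if profile["gender"] == "female":
            probs["D"] += 0.10
            probs["E"] += 0.04
            probs["B"] -= 0.10
            probs["A"] -= 0.04
        elif profile["gender"] == "male":
            probs["B"] += 0.12
            probs["D"] -= 0.10
            probs["E"] -= 0.02
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = np.maximum(p, 0.0)
    return cats, p / p.sum()


def _simulate_participant(pid: str, rng: np.random.Generator,
                          profile: dict[str, str], config: SimConfig):
    """One participant's sessions and truth rows; all times in float hours
    since the epoch.  *rng* is the participant's own stream, already used
    for the demographic draw, so demographics and behavior stay independent."""
    sleep, usage, checks, effects = (
        config.sleep, config.usage, config.night_checks, config.effects)

    # Participant-level latents.  z_gap drives earlier onset (larger gap);
    # z_use drives usage volume; they share the planted correlation.
    z_use = rng.normal()
    z_gap = (effects.usage_gap_rho * z_use
             + np.sqrt(max(0.0, 1 - effects.usage_gap_rho ** 2)) * rng.normal())
    # The male night-gap shift is a later sleep onset with wake unchanged
    # (onset +delta, duration -delta), so the planted shift survives window
    # clipping on both early- and late-waking nights.
    delta = (effects.male_onset_shift_hours
             if profile.get("gender") == "male" else 0.0)
    onset_mean = sleep.onset_mean_clock - sleep.onset_between_sd * z_gap + delta
    onset_mean = float(np.clip(onset_mean, *sleep.onset_bounds))
    kappa = sleep.trait_coupling
    z_dur = kappa * z_gap + np.sqrt(max(0.0, 1 - kappa ** 2)) * rng.normal()
    duration_mean = float(np.clip(
        sleep.duration_mean + sleep.duration_between_sd * z_dur - delta,
        *sleep.duration_bounds))
    rate = usage.session_rate_per_hour * max(0.2, 1.0 + usage.rate_rel_sd * z_use)
    inactive = usage.session_rate_per_hour <= 0  # rate 0: no app events at all

    day0 = (pd.Timestamp(config.start_date) - _EPOCH) / pd.Timedelta(hours=1)
    mean_len = float(np.exp(usage.session_len_log_mean
                            + usage.session_len_log_sd ** 2 / 2))

    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    truth_rows = []
    prev_wake = day0 + usage.first_day_start_clock
    for d in range(config.n_days):
        base = day0 + 24.0 * d
        onset = base + float(_trunc_normal(
            rng, onset_mean, sleep.onset_within_sd, *sleep.onset_bounds))
        duration = float(_trunc_normal(
            rng, duration_mean, sleep.duration_within_sd, *sleep.duration_bounds))

        # Daytime renewal process on [prev_wake, onset).
        span = max(0.0, onset - prev_wake)
        if inactive:
            s = e = np.empty(0)
        else:
            n_draw = int(rate * span * 2) + 8
            gaps = rng.exponential(1.0 / rate, size=n_draw)
            lens = rng.lognormal(usage.session_len_log_mean,
                                 usage.session_len_log_sd, size=n_draw)
            e = prev_wake + np.cumsum(gaps + lens)
            s = e - lens
            keep = s < onset
            s, e = s[keep], np.minimum(e[keep], onset)

        if effects.evening_coupling != 0.0:
            evening_start = base + 19.0
            ev = np.clip(e, evening_start, onset) - np.clip(s, evening_start, onset)
            expected = rate * mean_len * max(0.0, onset_mean - 19.0)
            excess = float(ev.sum()) - expected
            onset = float(np.clip(onset + effects.evening_coupling * excess,
                                  base + sleep.onset_bounds[0],
                                  base + sleep.onset_bounds[1]))
            keep = s < onset
            s, e = s[keep], np.minimum(e[keep], onset)

        wake = onset + duration

        if not inactive and rng.random() < usage.bedtime_use_prob:
            blen = float(np.clip(rng.lognormal(
                usage.session_len_log_mean, usage.session_len_log_sd),
                1 / 60, 0.5))
            s = np.append(s, onset - blen)
            e = np.append(e, onset)
        if not inactive and rng.random() < usage.wake_check_prob:
            delay = rng.uniform(0, usage.wake_check_delay_max_min / 60.0)
            clen = float(np.clip(rng.lognormal(
                usage.session_len_log_mean, usage.session_len_log_sd),
                0.5 / 60, 0.25))
            s = np.append(s, wake + delay)
            e = np.append(e, wake + delay + clen)
        if not inactive and duration > 1.5 and rng.random() < checks.prob_per_night:
            u = rng.uniform(onset + 0.5, wake - 0.5)
            clen = rng.uniform(checks.length_min_minutes,
                               checks.length_max_minutes) / 60.0
            s = np.append(s, u)
            e = np.append(e, u + clen)

        starts.append(s)
        ends.append(e)
        truth_rows.append((pid, d, onset, wake))
        prev_wake = wake

    s_all = np.concatenate(starts)
    e_all = np.concatenate(ends)
    order = np.argsort(s_all, kind="stable")
    s_all, e_all = s_all[order], e_all[order]

    cats, p = _mixture_for(profile, usage, effects)
    cat_idx = rng.choice(len(cats), size=s_all.size, p=p)
    app_idx = rng.integers(0, 10_000, size=s_all.size)
    apps = [APP_POOLS[cats[c]][a % len(APP_POOLS[cats[c]])]
            for c, a in zip(cat_idx, app_idx)]

    truth = pd.DataFrame(truth_rows,
                         columns=["participant_id", "day", "onset_h", "wake_h"])
    latent = {
        "participant_id": pid,
        "z_use": z_use,
        "z_gap": z_gap,
        "onset_mean_clock": onset_mean,
        "duration_mean_hours": duration_mean,
        "session_rate_per_hour": rate,
    }
    return s_all, e_all, apps, truth, latent


def true_sleep_in_window(night_truth: pd.DataFrame,
                         window: WindowSpec = WindowSpec()) -> pd.Series:
    """True sleep hours falling inside each night's analysis window."""
    base = (pd.to_datetime(night_truth["night_date"]) - _EPOCH) / pd.Timedelta(hours=1)
    w0 = base + window.start_clock
    w1 = base + 24.0 + window.end_clock
    onset = night_truth["onset_h"].to_numpy(float)
    wake = night_truth["wake_h"].to_numpy(float)
    return pd.Series(
        np.maximum(0.0, np.minimum(wake, w1) - np.maximum(onset, w0)),
        index=night_truth.index, name="true_sleep_in_window_hours")


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a full cohort: demographics, sessions, events and truth."""
    from .events import bin_age, events_from_sessions

    demo_rows = []
    sess_frames = []
    truth_frames = []
    latents = []
    day0_ts = pd.Timestamp(config.start_date)
    for i in range(config.n_participants):
        pid = f"p{i:05d}"
        rng = _participant_rng(config.seed, i)
        profile = _draw_profile(rng, config.composition)
        lo, hi = _AGE_RANGES[profile["age_range"]] \
            if profile["age_range"] in _AGE_RANGES else (18, 34)
        age = int(rng.integers(lo, hi + 1))
        demo_rows.append({
            "participant_id": pid,
            "gender": profile["gender"] if profile["gender"] != "excluded"
            else "Prefer not to answer",
            "age": age,
            "highest_degree": profile["highest_degree"]
            if profile["highest_degree"] != "excluded" else "Prefer not to answer",
            "employment": profile["employment"]
            if profile["employment"] != "excluded" else "Prefer not to answer",
            "use_type": profile.get("use_type", "private_only"),
        })
        s, e, apps, truth, latent = _simulate_participant(pid, rng, profile, config)
        sess_frames.append(pd.DataFrame({
            "participant_id": pid,
            "app_id": apps,
            "start_h": s,
            "end_h": e,
        }))
        truth_frames.append(truth)
        latents.append(latent)

    demographics = pd.DataFrame(demo_rows)
    sessions = pd.concat(sess_frames, ignore_index=True)
    # Snap to second resolution (the event-log format); drop sub-second slivers.
    start_ts = pd.to_datetime(np.round(sessions["start_h"] * 3600.0), unit="s")
    end_ts = pd.to_datetime(np.round(sessions["end_h"] * 3600.0), unit="s")
    sessions = pd.DataFrame({
        "participant_id": sessions["participant_id"],
        "app_id": sessions["app_id"],
        "start": start_ts,
        "end": end_ts,
    })
    sessions = sessions[sessions["end"] > sessions["start"]].reset_index(drop=True)

    night_truth = pd.concat(truth_frames, ignore_index=True)
    night_truth["night_date"] = day0_ts + pd.to_timedelta(night_truth["day"], unit="D")
    night_truth["onset"] = pd.to_datetime(
        np.round(night_truth["onset_h"] * 3600.0), unit="s")
    night_truth["wake"] = pd.to_datetime(
        np.round(night_truth["wake_h"] * 3600.0), unit="s")
    night_truth["true_sleep_in_window_hours"] = true_sleep_in_window(night_truth)
    night_truth = night_truth[
        ["participant_id", "night_date", "onset", "wake",
         "onset_h", "wake_h", "true_sleep_in_window_hours"]]

    participant_truth = pd.DataFrame(latents)

    # Normalized profiles via the same path real surveys take.
    from .events import (DEGREE_LEVELS, EMPLOYMENT_LEVELS, GENDER_LEVELS,
                         USE_TYPE_LEVELS, _GENDER_MAP, _DEGREE_MAP,
                         _EMPLOYMENT_MAP, _USE_TYPE_MAP, _normalize_categorical)
    profiles = pd.DataFrame({
        "participant_id": demographics["participant_id"],
        "gender": _normalize_categorical(
            demographics["gender"], _GENDER_MAP, GENDER_LEVELS),
        "age_range": bin_age(demographics["age"]),
        "highest_degree": _normalize_categorical(
            demographics["highest_degree"], _DEGREE_MAP, DEGREE_LEVELS),
        "employment": _normalize_categorical(
            demographics["employment"], _EMPLOYMENT_MAP, EMPLOYMENT_LEVELS),
        "use_type": _normalize_categorical(
            demographics["use_type"], _USE_TYPE_MAP, USE_TYPE_LEVELS),
    })

    events = events_from_sessions(sessions)
    return SimResult(config, demographics, profiles, sessions, events,
                     night_truth, participant_truth)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demographics table plus participant-level ground truth only."""
    result = simulate_cohort(dataclasses.replace(config, n_days=1))
    return result.demographics, result.participant_truth


def write_cohort(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, demographics.csv and truth.csv for a cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out_dir / "events.csv",
        "demographics": out_dir / "demographics.csv",
        "truth": out_dir / "truth.csv",
    }
    ev = result.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(paths["events"], index=False)
    result.demographics.to_csv(paths["demographics"], index=False)
    truth = result.night_truth.copy()
    truth["night_date"] = truth["night_date"].dt.strftime("%Y-%m-%d")
    for col in ("onset", "wake"):
        truth[col] = truth[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    truth.to_csv(paths["truth"], index=False, float_format="%.6f")
    return paths
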