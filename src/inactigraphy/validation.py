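"""Monte-Carlo validation experiments for the pipeline.

Each function runs one planned experiment against the synthetic cohort
generator's ground truth and returns the measured quantity: the agreement
of the gap statistic with a brute-force scan, the type-I error and power of
the comparison battery, the fidelity of the sleep proxy, and the recovery
of a planted usage–sleep correlation.  Problem sizes are chosen so each
experiment completes in minutes on one CPU; the seeds fan out from one
master seed so every experiment is reproducible end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import compare_groups, kruskal_wallis
from .metrics import daily_usage_table, participant_usage_summary
from .nights import WindowSpec, longest_inactivity_gap, night_records, \
    summarize_participant_nights
from .simulate import DEFAULT_COMPOSITION, NightCheckModel, SleepModel, \
    scenario, simulate_cohort
from .taxonomy import default_mapping

_EPOCH = pd.Timestamp("1970-01-01")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


#: Fixed experiment order; each validation experiment gets its own child
#: seed from the master so the experiments stay mutually independent.
EXPERIMENTS = ("gap_oracle", "type_i", "power", "proxy", "recovery")


def experiment_seeds(master_seed: int) -> dict[str, int]:
    children = _child_seeds(master_seed, len(EXPERIMENTS))
    return {name: int(s) for name, s in zip(EXPERIMENTS, children)}


def brute_force_gap(starts_min: np.ndarray, ends_min: np.ndarray,
                    window_minutes: int = 660) -> float:
    """Minute-resolution oracle: scan window minutes for coverage and track
    the longest uncovered run.  Exact for minute-aligned activity."""
    covered = np.zeros(window_minutes, dtype=bool)
    for s, e in zip(starts_min, ends_min):
        lo = max(0, int(np.floor(s)))
        hi = min(window_minutes, int(np.ceil(e)))
        if hi > lo:
            covered[lo:hi] = True
    longest = run = 0
    for c in covered:
        run = 0 if c else run + 1
        longest = max(longest, run)
    return longest / 60.0


def gap_oracle_max_error(n_nights: int = 1000, seed: int = 0) -> float:
    """Max |implementation − brute force| over random minute-aligned nights."""
    rng = np.random.default_rng(seed)
    window = WindowSpec()
    night = pd.Timestamp("2022-06-01")
    win_start = night + pd.Timedelta(hours=window.start_clock)
    worst = 0.0
    for _ in range(n_nights):
        n_act = int(rng.integers(0, 12))
        s_min = np.sort(rng.integers(-120, 720, size=n_act))  # may straddle edges
        lengths = rng.integers(1, 90, size=n_act)
        e_min = s_min + lengths
        activity = pd.DataFrame({
            "participant_id": "p0",
            "start": win_start + pd.to_timedelta(s_min, unit="m"),
            "end": win_start + pd.to_timedelta(e_min, unit="m"),
        })
        got = longest_inactivity_gap(activity, night, window)
        want = brute_force_gap(s_min.astype(float), e_min.astype(float))
        worst = max(worst, abs(got - want))
    return worst


def _draw_null_gap_means(rng: np.random.Generator, n: int, n_nights: int,
                         sleep: SleepModel = SleepModel()) -> np.ndarray:
    """Participant mean nightly gaps under the null sleep model.

    The nightly gap is, to first order, the time from sleep onset to the
    06:00 window edge (wake falls beyond it on most nights), clipped to the
    window; this reproduces the null gap distribution without simulating
    event streams.
    """
    onset_mean = np.clip(
        rng.normal(sleep.onset_mean_clock, sleep.onset_between_sd, size=n),
        *sleep.onset_bounds)
    onset = np.clip(
        rng.normal(onset_mean[:, None], sleep.onset_within_sd, size=(n, n_nights)),
        *sleep.onset_bounds)
    gaps = np.clip(30.0 - onset, 0.0, 11.0)
    return gaps.mean(axis=1)


def kw_null_rejection_rate(n_reps: int = 2000, k: int = 3, n_per_group: int = 50,
                           n_nights: int = 3, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Empirical type-I error of the Kruskal–Wallis test at level *alpha*.

    All groups are drawn from the one null-scenario gap distribution, so
    the rejection rate should sit at *alpha*.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        values = _draw_null_gap_means(rng, k * n_per_group, n_nights)
        groups = np.split(values, k)
        if kruskal_wallis(groups).p_value < alpha:
            rejections += 1
    return rejections / n_reps


def _balanced_gender_config(name: str, n_per_group: int, n_days: int, seed: int):
    comp = {key: dict(val) for key, val in DEFAULT_COMPOSITION.items()}
    comp["gender"] = {"female": 0.5, "male": 0.5}
    cfg = scenario(name, n_participants=2 * n_per_group, n_days=n_days, seed=seed)
    return dataclasses.replace(cfg, composition=comp)


def gender_gap_power(n_reps: int = 500, n_per_group: int = 150, n_days: int = 3,
                     alpha: float = 0.05, seed: int = 0) -> float:
    """Power of the comparison battery against the planted −0.5 h male
    nightly-gap shift, with the full event-level pipeline per replicate."""
    seeds = _child_seeds(seed, n_reps)
    rejections = 0
    for rep_seed in seeds:
        cfg = _balanced_gender_config("gender_gap", n_per_group, n_days,
                                      int(rep_seed))
        res = simulate_cohort(cfg)
        recs = night_records(res.sessions, events=res.events)
        summaries = summarize_participant_nights(recs)
        result = compare_groups(
            summaries[["participant_id", "mean_gap_hours"]], res.profiles,
            "gender", "mean_gap_hours")
        if result.p_value < alpha:
            rejections += 1
    return rejections / n_reps


def sleep_proxy_correlation(n_participants: int = 200, n_days: int = 14,
                            seed: int = 0) -> float:
    """Pearson r between true in-window sleep and the estimated gap,
    night-by-night, in a cohort without nocturnal phone checks."""
    cfg = scenario("null", n_participants=n_participants, n_days=n_days, seed=seed)
    cfg = dataclasses.replace(cfg, night_checks=NightCheckModel(prob_per_night=0.0))
    res = simulate_cohort(cfg)
    recs = night_records(res.sessions, events=res.events)
    merged = recs.merge(res.night_truth, on=["participant_id", "night_date"])
    r, _ = stats.pearsonr(merged["longest_gap_hours"],
                          merged["true_sleep_in_window_hours"])
    return float(r)


def coupling_recovery(n_seeds: int = 100, n_participants: int = 150,
                      n_days: int = 14, rho: float = -0.6, tol: float = 0.12,
                      seed: int = 0) -> tuple[float, np.ndarray]:
    """Recovery of the planted usage–gap correlation across seeds.

    Runs the full pipeline (events → sessions → daily usage → night gaps →
    participant-level Pearson r) per seed; returns the fraction of seeds
    whose estimate lands within *tol* of *rho*, plus all estimates.
    """
    mapping = default_mapping()
    seeds = _child_seeds(seed, n_seeds)
    estimates = []
    for rep_seed in seeds:
        cfg = scenario("usage_sleep_coupling", n_participants=n_participants,
                       n_days=n_days, seed=int(rep_seed))
        res = simulate_cohort(cfg)
        daily = daily_usage_table(res.sessions, mapping)
        usage = participant_usage_summary(daily)
        recs = night_records(res.sessions, events=res.events)
        summaries = summarize_participant_nights(recs)
        merged = usage.merge(summaries, on="participant_id")
        r, _ = stats.pearsonr(merged["mean_total_hours"], merged["mean_gap_hours"])
        estimates.append(float(r))
    estimates = np.array(estimates)
    return float(np.mean(np.abs(estimates - rho) <= tol)), estimates
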