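"""Association between daytime usage and nocturnal inactivity.

Simulates a cohort with a planted participant-level correlation of -0.6
between usage volume and the night gap, runs the full pipeline to
participant-level summaries, and reports per-gender correlation and
regression of mean gap on mean daily usage.
"""

import inactigraphy as ig

cfg = ig.scenario("usage_sleep_coupling", n_participants=150, n_days=14, seed=2)
cohort = ig.simulate_cohort(cfg)
mapping = ig.default_mapping()

daily = ig.daily_usage_table(cohort.sessions, mapping)
usage = ig.participant_usage_summary(daily)
nights = ig.night_records(cohort.sessions, events=cohort.events)
summaries = ig.summarize_participant_nights(nights)

res = ig.subgroup_associations(usage, summaries, cohort.profiles, "gender")
totals = res[res["predictor"] == "total"]
print(totals[["subgroup", "n", "r", "p", "slope", "intercept", "r_squared"]]
      .round(3).to_string(index=False))

print(
    "\nEach row correlates a subgroup's mean daily usage hours with its\n"
    "mean nightly inactivity gap: r near -0.6 recovers the planted\n"
    "coupling (heavier users go to sleep later, shrinking the gap), and\n"
    "the regression slope gives hours of lost gap per extra usage hour."
)
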