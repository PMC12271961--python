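"""Daily usage metrics on a small synthetic cohort.

Simulates 10 participants for 7 days, computes per-day usage (interval
union of sessions plus per-category sums) and per-participant summaries,
and prints the cohort-level category shares.
"""

import inactigraphy as ig

cfg = ig.scenario("null", n_participants=10, n_days=7, seed=42)
cohort = ig.simulate_cohort(cfg)
mapping = ig.default_mapping()

daily = ig.daily_usage_table(cohort.sessions, mapping)
summary = ig.participant_usage_summary(daily)

print("per participant-day (first rows):")
print(daily[["participant_id", "date", "total_hours", "session_count"]]
      .head(5).to_string(index=False))

print("\nper participant:")
print(summary[["participant_id", "n_days", "mean_total_hours",
               "median_total_hours"]].head(5).to_string(index=False))

print("\ncategory shares (duration basis):")
print(ig.compute_category_shares(daily, basis="duration").round(3).to_string())

print(
    "\ntotal_hours is the union of the day's session intervals, so it can\n"
    "never exceed 24 h even when records overlap; shares say what fraction\n"
    "of summed app time each functional category (A network, B leisure,\n"
    "C utility, D social, E monetary) accounts for."
)
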