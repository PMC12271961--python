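"""Demographic comparison battery on a cohort with a planted gender gap.

Simulates a cohort where male participants fall asleep half an hour later
(shifting their nightly gap down 0.5 h), then runs the Kruskal-Wallis test
with Dunn post hoc on the participant-level mean gap.
"""

import dataclasses

import inactigraphy as ig
from inactigraphy.simulate import DEFAULT_COMPOSITION

comp = {k: dict(v) for k, v in DEFAULT_COMPOSITION.items()}
comp["gender"] = {"female": 0.5, "male": 0.5}
cfg = dataclasses.replace(
    ig.scenario("gender_gap", n_participants=200, n_days=5, seed=1),
    composition=comp)

cohort = ig.simulate_cohort(cfg)
nights = ig.night_records(cohort.sessions, events=cohort.events)
summaries = ig.summarize_participant_nights(nights)

result = ig.compare_groups(
    summaries[["participant_id", "mean_gap_hours"]],
    cohort.profiles, "gender", "mean_gap_hours")

print(result.summary[["level", "n", "median", "q1", "q3"]].round(2)
      .to_string(index=False))
print(f"\nKruskal-Wallis H = {result.H:.2f} on {result.df} df, "
      f"p = {result.p_value:.2e}")
print("\nDunn post hoc (Holm-adjusted):")
print(result.pairwise.round(4).to_string(index=False))

print(
    "\nThe male median nightly gap sits about half an hour below the female\n"
    "median — the planted effect — and the rank test flags the difference."
)
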