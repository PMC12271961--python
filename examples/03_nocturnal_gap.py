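"""The nocturnal inactivity gap: the package's sleep-proxy statistic.

Builds one participant-night by hand — last phone use ends 22:45, a brief
wake-up check at 07:30 next morning — and shows the longest inactivity gap
inside the 19:00-06:00 window, plus the adequate-sleep classification.
"""

import pandas as pd

import inactigraphy as ig

base = pd.Timestamp("2022-03-01")
sessions = pd.DataFrame({
    "participant_id": "p1",
    "app_id": ["youtube", "whatsapp", "clock"],
    "start": [base + pd.Timedelta(hours=h) for h in (21.0, 22.5, 31.5)],
    "end": [base + pd.Timedelta(hours=h) for h in (21.5, 22.75, 31.6)],
})

gap = ig.longest_inactivity_gap(sessions, "2022-03-01")
print(f"longest nocturnal inactivity gap: {gap:.2f} h")
print(f"adequate sleep (>= 6 h threshold): {ig.classify_night(gap, 6.0)}")

nights = ig.night_records(sessions)
print("\nall evaluated nights:")
print(nights.to_string(index=False))

print(
    "\nThe gap runs from the last evening use (22:45) to the 06:00 window\n"
    "edge: 7.25 h, a proxy for the sleep window. The 07:30 wake-up check\n"
    "falls outside the window and does not shorten it. The flanking nights\n"
    "show 11 h (the full window): they touch a recorded day, so they are\n"
    "evaluated, but no activity falls inside their windows."
)
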