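"""Turn a raw smartphone event log into foreground app sessions.

Builds a six-event log for one participant, including a foreground switch
(a new app starting while another is open) and an orphan end event, then
prints the derived sessions.
"""

import io

import pandas as pd

import inactigraphy as ig

log = io.StringIO("""participant_id,timestamp,event_type,app_id
p1,2022-03-01T09:00:00,screen_on,
p1,2022-03-01T09:00:05,app_start,whatsapp
p1,2022-03-01T09:04:00,app_start,youtube
p1,2022-03-01T09:30:00,app_end,youtube
p1,2022-03-01T09:30:02,screen_off,
p1,2022-03-01T10:15:00,app_end,spotify
""")

events = pd.read_csv(log, dtype=str)
events["timestamp"] = pd.to_datetime(events["timestamp"])
sessions = ig.build_sessions(events)

print(sessions.to_string(index=False))
print(f"\nsessionization warnings: {sessions.attrs['n_warnings']}")
print(
    "\nThe whatsapp session is closed at 09:04 because youtube takes the\n"
    "foreground (only one app is foreground at a time); the dangling\n"
    "spotify end event has no matching start and is ignored with a warning."
)
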