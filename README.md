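# inactigraphy

Sleep-proxy analytics from smartphone event logs.

Passively collected smartphone interaction data — screen on/off events and
foreground app sessions — carry a strong behavioral signature of sleep:
most people stop touching their phone when they fall asleep and pick it up
again when they wake. `inactigraphy` turns raw per-participant event
streams into that signal. It is written for researchers in digital
phenotyping, sleep epidemiology and mobile sensing who need a reproducible
pipeline from event CSVs to stratified statistical tables, without wearable
or polysomnography data.

## What it computes

**Nocturnal inactivity gap.** For each participant-night, the longest
continuous period with no smartphone activity inside a wall-clock window
from 19:00 on day *d* to 06:00 on day *d+1* (an 11-hour window; all
intervals half-open). A night whose gap reaches the 6-hour threshold
(inclusive) counts as adequate-sleep; nights below it flag potential sleep
deprivation. Participants with no adequate night over their recording
period form **group 1**, all others **group 2**. Window edges and threshold
are configurable (`WindowSpec`).

**Usage metrics.** Per participant-day: total usage as the *interval union*
of foreground sessions (so duplicated or overlapping records can never
exceed 24 h/day), session counts, and per-category durations/counts over a
six-way functional app taxonomy (A network/information, B leisure,
C utility, D social, E monetary, unknown).

**Comparison battery.** Medians with first/third quartiles per demographic
stratum (gender, age range, highest degree, employment, smartphone use
type), Shapiro–Wilk and Brown–Forsythe screening, the tie-corrected
Kruskal–Wallis test

&nbsp;&nbsp;&nbsp;&nbsp;H = [12 / (N(N+1))] Σᵢ nᵢ (r̄ᵢ − (N+1)/2)² / (1 − ΣT/(N³−N)),&nbsp;&nbsp;T = t³ − t per tie group,

with a χ²(k−1) reference, and Dunn's post hoc pairwise z

&nbsp;&nbsp;&nbsp;&nbsp;z₍ᵢⱼ₎ = (r̄ᵢ − r̄ⱼ) / √[(N(N+1)/12 − ΣT/(12(N−1))) (1/nᵢ + 1/nⱼ)],

Holm-adjusted by default.

**Associations.** Per-subgroup Pearson (or Spearman) correlation and simple
OLS regression of each participant's mean nightly gap on mean daily usage,
total and per category, reported as r, p, slope, intercept, R².

**Synthetic cohorts.** A generator with known ground truth — truncated
normal sleep windows, a daytime session renewal process, phone-in-bed and
wake-check anchoring, occasional nocturnal checks, realistic demographic
composition — plus named scenarios (`null`, `gender_gap`,
`usage_sleep_coupling`, `taxonomy_mixture`) that plant effects for
validation.

## Worked example

```python
import pandas as pd
import inactigraphy as ig

base = pd.Timestamp("2022-03-01")
sessions = pd.DataFrame({
    "participant_id": "p1",
    "app_id": ["youtube", "whatsapp", "clock"],
    "start": [base + pd.Timedelta(hours=h) for h in (21.0, 22.5, 31.5)],
    "end":   [base + pd.Timedelta(hours=h) for h in (21.5, 22.75, 31.6)],
})
gap = ig.longest_inactivity_gap(sessions, "2022-03-01")
print(f"longest nocturnal inactivity gap: {gap:.2f} h")
print(f"adequate sleep (>= 6 h threshold): {ig.classify_night(gap, 6.0)}")
```

prints

```
longest nocturnal inactivity gap: 7.25 h
adequate sleep (>= 6 h threshold): True
```

The participant's last evening use ends 22:45; nothing happens until a
07:30 wake-up check, which lies outside the window, so the gap runs from
22:45 to the 06:00 window edge — 7.25 h, above the 6-hour threshold.

The `examples/` directory holds one short script per capability
(sessionization, usage metrics, the gap statistic, group comparison,
associations, the full pipeline); each prints the numbers it computes and a
line on what they mean. The same pipeline is scriptable from the shell:

```bash
inactigraphy simulate --scenario gender_gap --n 200 --days 7 --seed 1 --out-dir cohort/
inactigraphy report cohort/events.csv cohort/demographics.csv --out-dir report/
```

## Layout

```
src/inactigraphy/
  events.py      event model, readers, sessionization
  taxonomy.py    six-way functional app categories
  metrics.py     daily usage durations, counts, shares
  nights.py      nocturnal inactivity gap and stratification
  comparison.py  median/IQR, Kruskal-Wallis, Dunn, screening tests
  association.py correlation and simple regression per subgroup
  simulate.py    synthetic cohorts with ground truth
  validation.py  Monte-Carlo validation experiments
  pipeline.py    three-phase orchestration and report tables
  cli.py         thin command-line layer
docs/methods.md  model, assumptions, parameter choices, limitations
```
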