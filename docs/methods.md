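# Methods

## The sleep proxy

The package's central quantity is the **nocturnal inactivity gap**: for a
participant-night *d*, the length of the longest maximal sub-interval of
the clock window [*d* 19:00, *d+1* 06:00) not covered by smartphone
activity. Activity is the union of foreground app sessions by default;
screen-on intervals are available as an alternative basis
(`activity_basis="screen"`). All intervals are half-open [start, end), so
a session ending exactly at 19:00 contributes nothing to the window, and
gaps truncated by a window edge count at their truncated length. With no
activity in the window the gap is the full window length (11 h by
default).

The proxy rests on a behavioral assumption, not a physiological one: the
phone is untouched while its owner sleeps. It overestimates sleep when the
evening ends with non-phone activities and underestimates it when sleep is
interrupted by phone checks; neither failure mode is modeled away, they
are simply what the statistic measures. A gap of at least 6 h (inclusive)
marks an adequate-sleep night, mirroring the common short-sleep cutoff;
participants whose recording period contains no adequate night form
group 1, the rest group 2.

**Night eligibility.** A night *d* is evaluated only if the participant
produced at least one event on day *d* or day *d+1*. Recording periods
vary by participant, and a silent night inside a non-recording stretch is
indistinguishable from the collection app being off; counting it as 11 h
of inactivity would manufacture sleep out of missing data. The rule still
admits boundary nights (the night before the first recorded day touches
it), which read as full-window gaps; they are genuine "no activity
observed in window" records, and analyses on participant summaries should
be aware of them.

## Usage metrics

Total daily usage is the length of the interval union of that day's
sessions — the only definition that guarantees a daily total of at most
24 h under overlapping or duplicated records. Per-category durations are
plain sums within category, so their total may exceed the union; category
shares divide per-category sums by the all-category sum, on either a
duration or a launch-frequency basis (both are reported because the two
answer different questions and real report tables are often ambiguous
between them). Sessions crossing midnight are split at midnight before
duration aggregation; counts attribute each session to its start day, so
splitting a session at an interior point changes no duration metric and
the count convention is explicit. Days with no recorded events are
treated as non-recording, not as zero use, and are excluded from
per-participant averages.

Sessionization follows foreground exclusivity: an `app_start` closes any
open session at its own timestamp, an `app_end` closes the matching open
session, a dangling open session is closed at the participant's last
event, zero-length sessions are dropped, and sessions longer than 24 h
are rejected as corrupt (a lost end event otherwise fabricates a day of
use). Orphan `app_end` events are ignored with a warning.

## Statistical battery

Usage and gap variables are skewed and tied, so group comparisons are
nonparametric throughout: medians with first/third quartiles
(linear-interpolation quantiles, the numpy default, so R and Python
implementations agree), the tie-corrected Kruskal–Wallis H with a
χ²(k−1) reference, and Dunn's pairwise z with the pooled tie term and
Holm adjustment (Bonferroni and unadjusted available). Shapiro–Wilk and
Brown–Forsythe (median-centered Levene) results are reported per stratum
as screening information but never gate the rank test. A pooled sample
with a single distinct value is degenerate: H = 0, p = 1, flagged. A
permutation mode for Kruskal–Wallis exists for very small samples
(n ≲ 30); the χ² reference is the default. For k = 2 the implementation's
H, Dunn z and the tie-corrected normal-approximation Mann–Whitney test
agree to machine precision, which the tests assert.

Associations use the participant as the unit of analysis: each
contributes (mean daily usage, mean nightly gap). Pearson correlation is
the default, Spearman available for heavily skewed subgroups; the
regression is simple OLS with the t-based slope p on n−2 df, and R²
equals r² by construction. Subgroups with fewer than 3 joinable
participants are skipped with a warning. Raw p values are reported by
default (matching common practice in descriptive association grids);
Benjamini–Hochberg adjustment over the subgroup × predictor grid is a
flag. No multiplicity adjustment is applied across the comparison
battery's variable × grouping grid either — the tables are descriptive,
and the choice is documented rather than hidden.

## App taxonomy

Apps map case-insensitively onto six functional categories: A
network/information, B leisure-entertainment, C functional utilities, D
emotional/social, E monetary, and unknown for everything unmapped, so
classification is total. A small default mapping of well-known apps is
bundled for examples and simulation; any real analysis should supply its
own mapping CSV (`--mapping`), since app catalogs are vast and
fast-moving.

## Synthetic cohort generator

The generator exists so that every pipeline stage can be validated
against known ground truth. Per participant it draws:

- **Demographics** from a composition mirroring a large German
  convenience cohort (two-thirds female, predominantly 18–35,
  student-heavy, with survey non-response as its own `excluded` level).
- **Sleep**: a stable participant mean onset (default 23:15, between-
  participant SD 0.75 h, truncated to 20:30–02:30) and mean duration
  (7.5 ± 0.75 h, truncated 3.5–10.5 h), with nightly noise (SD 0.5 h
  each). A "morningness" trait correlation of 0.6 makes earlier sleepers
  sleep longer, so a participant's latent sleep trait expresses itself in
  the night gap whether or not the wake time is clipped by the 06:00
  window edge.
- **Daytime usage**: a renewal process over the waking span (exponential
  inter-arrivals, default 3.2 sessions/h scaled by a participant-level
  volume factor; log-normal session lengths, median ≈3 min), yielding
  roughly 3–3.5 h of daily use. Sessions are clipped at sleep onset and
  never intrude into the sleep interval.
- **Anchoring behavior**: with probability 0.9 a phone-in-bed session ends
  exactly at sleep onset, and with probability 0.9 a brief check follows
  waking within 5 min — the empirically common pattern that makes the
  inactivity gap a sharp sleep proxy. Nocturnal checks (probability 0.15
  per night, 1–5 min, placed uniformly inside sleep) are the only
  activity allowed to overlap sleep.
- **Category choice** per session from a social-media-heavy mixture,
  with app names drawn from pools matching the bundled taxonomy.

Event streams are emitted at second resolution as `app_start`/`app_end`
rows; ground truth (true onset, wake, in-window sleep per night; latent
volume and sleep traits per participant) is returned alongside. Each
participant owns a pseudo-random stream keyed by (master seed,
participant index), so enlarging a cohort never reshuffles existing
participants, and a fixed seed reproduces outputs byte for byte.

**Scenarios.** `null` switches every planted effect off. `gender_gap`
delays male sleep onset by 0.5 h with wake unchanged, shifting the male
nightly gap distribution down by exactly 0.5 h in both window-clipped and
unclipped regimes. `usage_sleep_coupling` draws each participant's usage
volume and sleep-timing latents from a bivariate normal with correlation
−0.6, with usage linear in its latent so Pearson correlation survives the
mapping; a separate optional mechanism (`evening_coupling`) lets excess
evening use delay that night's onset. `taxonomy_mixture` shifts the app
category mixture by gender (female social/monetary-heavy, male
entertainment-heavy).

**What the generator does not emulate**: real cohorts' irregular
recording coverage, timezone travel, shared devices, weekday/weekend
structure, app-level heterogeneity beyond category pools, or any fit to a
particular study's empirical distributions beyond qualitative structure.
Passing validation therefore shows the pipeline recovers what it is
pointed at under clean recording assumptions, not that any particular
real-world cohort satisfies them.

## Validation experiments

The experiments in `inactigraphy.validation` (run by the test suite and
by `scripts/acceptance.py`) use these problem sizes, chosen to finish in
minutes on one CPU while leaving clear statistical margins:

- **Gap oracle**: 1,000 random minute-aligned nights against a
  minute-resolution coverage scan; agreement within 1/60 h.
- **Type-I error**: 2,000 replicates of k = 3 groups × 50 participants,
  3 nights each, drawn from the null sleep model at the participant-
  summary level (this isolates the rank test itself; full event-level
  nulls are exercised separately in the unit tests at smaller replicate
  counts).
- **Power**: 500 full event-level pipeline replicates of the gender-gap
  scenario at 150 per group × 3 nights.
- **Sleep proxy**: 200 participants × 14 nights without nocturnal
  checks; night-level Pearson r between true in-window sleep and the
  estimated gap.
- **Correlation recovery**: 100 seeds × (150 participants × 14 days) of
  the coupling scenario through the full pipeline; fraction of seeds with
  the estimated r within ±0.12 of −0.6. At this sample size the Fisher
  sampling SD of r is ≈0.053, so the ±0.12 band is ≈2.3σ — the
  experiment runs close to its own noise floor by construction.
- **Golden run**: the bundled 6-participant, 3-day toy cohort (generated
  at a reduced session rate to stay small) must reproduce the checked-in
  report tables byte-exactly; report CSVs are written with fixed float
  precision and fixed row order to make that meaningful.

## Numerical and edge-case choices

- Timestamps are naive local clock times; the night window is a
  wall-clock construct, so no timezone or DST arithmetic is performed.
- Quantiles: linear interpolation between order statistics everywhere.
- Threshold comparison is inclusive at exactly 6.0 h.
- Zero-variance inputs: correlation raises an error naming the degenerate
  side; a flat regression response returns slope 0, R² 0; a constant
  sample is flagged degenerate by the normality check rather than tested.
- Report tables round percentages to one decimal and write floats with
  four decimals; cohort-table rows follow the fixed enum order of the
  demographic levels, with survey non-response (`excluded`) as its own
  row, excluded from inferential analyses.
- Demographic tokens outside the recognized vocabularies ("Other",
  "Prefer not to answer", "Unknown", typos) normalize to `excluded`.

## Known limitations

- The gap statistic is a behavioral proxy; no claim is made that it
  equals physiological sleep, and no sleep-stage modeling is attempted.
- Boundary nights at the edges of a recording period read as full-window
  gaps (see night eligibility above).
- The bundled app taxonomy covers only well-known apps; everything else
  is `unknown` until a study-specific mapping is supplied.
- Whether "usage" should mean app-foreground time or screen-on time is a
  data-availability question; both bases are implemented, with
  app-foreground as the default and richer of the two in the event model.
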