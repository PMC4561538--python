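# Methods

This note documents the models and rules the package implements, the
defaults it ships, the design choices made where the published instrument
leaves the design open, and what the synthetic-data experiments do and do
not demonstrate.

## Audit model and scoring

An audit dataset is one route per participant, each route holding one set
of route-level responses, one or more street-segment observations, and zero
or more crossing observations. Raw responses are recorded directly on the
item's score scale (0/1 or 0/1/2); missing responses are a distinct state,
never conflated with 0, and round-trip through CSV as empty cells.

Per-item participant scores are the single route-level response or the
arithmetic mean over segments/crossings with a non-missing response. The
total is the sum of item scores over the items included in the total;
percent-of-max divides by the corresponding sum of item maxima.

Decisions where the instrument's published description is open:

* **Item catalog.** The instrument publishes the 15 item names and that
  items are scored 0–1 or 0–1–2, but not the per-item ranges of the 14
  retained items. The default catalog is binary for all items except the
  bicycle-facility item (0–1–2); the catalog is YAML-editable, and the
  level at which each streetscape item is observed (street lights and
  benches default to segment level; park, transit, aesthetics, and the
  bike item to route level) is likewise a documented, editable assumption.
* **Total-score composition.** The default total uses the 12 items of the
  validation analyses: the 14 tabled items minus the two aesthetics/social
  items (building maintenance, absence of graffiti), bike item excluded.
  `ScoreConfig(include_bike_in_total=True)` adds the 0–2 bike item for
  instrument use.
* **Missing items.** The default policy renormalizes: an in-total item
  with no observations (crossing items on a crossing-free route) is
  dropped from both numerator and denominator, keeping percent-of-max on a
  common 0–100 scale across route topologies. `missing_policy="fail"`
  makes such routes an error instead.
* **Quintiles.** Ranks use average-rank tie handling, quintile =
  ceil(5·rank/n); tied scores therefore always share a quintile, and a
  fully tied sample lands in quintile 3. Scores are carried at full float
  precision; percentages are formatted to one decimal only in reports.

## Accelerometry

* **Non-wear**: every maximal run of consecutive zero-count epochs lasting
  at least the window is non-wear; windows default to 20/30/45 minutes for
  children/adolescents/older adults. A single non-zero epoch terminates a
  run; no interruption allowance and no spike filtering, keeping the rule
  transparent and exactly testable against run-length enumeration.
* **Valid day**: wear minutes over the whole calendar day ≥ 600 (10 h,
  boundary inclusive). The windowed/neighborhood MVPA fields restrict
  which epochs contribute activity, not the wear-time denominator.
* **MVPA**: wear epochs whose counts-per-minute meet the cut point; 30-s
  epoch counts are doubled onto the counts/min scale rather than
  re-integrated to 60-s epochs (switchable by pre-aggregating). Cut points
  are configuration: defaults are the Freedson adult 1952 counts/min
  (3 METs) for older adults and the Freedson/Trost youth regression
  `METs = 2.757 + 0.0015·cpm − 0.08957·age − 0.000038·cpm·age` solved at
  3 METs (children) or 4 METs (adolescents) for the participant's age.
  These defaults are provisional conveniences — the protocol names the cut
  point families but not numeric thresholds — and should be overridden
  when a study specifies its own.
* **Windows**: the non-school filter keeps weekday epochs starting in
  [15:00, 23:00) plus all weekend (Sat/Sun local) epochs; neighborhood
  linkage keeps epochs whose start lies in a reported [start, end)
  interval. Both conventions are half-open on the right.
* **Participant summaries**: mean daily MVPA over valid days only; a
  participant with no valid day is excluded (`None`), never scored zero.

## Outcomes and analysis table

Transport and leisure outcomes are selected per age group (youth: means of
0–5 ordinal frequency items, analyzed as numeric — a limitation inherited
from the instrument's response scales; adults: GPAQ days and minutes;
older adults: CHAMPS items). The MVPA outcome maps child → neighborhood
MVPA, adolescent → non-school MVPA, older adult → total MVPA, adult →
absent. Covariate-incomplete rows are retained in the table with a flag
and excluded from the model-ready view (listwise deletion at modeling
time).

## Mixed models

Each association is a linear mixed model with a random intercept per
census block group, fit by REML (statsmodels `MixedLM`). The predictor's
test is Wald: t = β̂/SE with a two-sided normal-approximation p. With the
cluster counts these designs use (tens of block groups), the normal
approximation is adequate; a Satterthwaite refinement was considered and
left out to keep a single well-defined p-value definition. The total-score
row uses percent-of-max as predictor (the t statistic is invariant to the
linear rescaling between total and percent). No multiple-testing
correction is applied by default, matching per-test α = 0.05 reporting; a
Benjamini–Hochberg helper is available. Cells the study design leaves
empty — all adult MVPA cells, and the commercial item for older adults —
are explicit not-available records excluded from significance
denominators. Non-convergence or numerical failure is recorded per cell
and never silently dropped.

## Synthetic-data generator

The generator emulates the study design the analysis assumes:

* block groups stratified by a binary walkability index (default 100
  block groups, half high-walkability);
* cohorts of 758/897/1655/367 children/adolescents/adults/older adults by
  default (scalable), assigned uniformly to block groups, with nonwhite
  fractions 31.4/33.3/24.2/16.2% and age ranges per group;
* routes with 1 + Poisson(2) segments and Poisson(1.5) crossings (so
  roughly a fifth of routes have no crossings and exercise
  renormalization), item responses Bernoulli with stratum-dependent
  prevalence (bike item categorical). Default prevalences put most routes
  well under half the maximum score with a wide spread, echoing how real
  streetscape audits distribute;
* survey outcomes from the latent linear model
  y = β₀ + β_score·percent + γ'z + b_bg + ε with b_bg ~ N(0, τ²),
  ε ~ N(0, σ²), then mapped to the instrument scale (ordinal 0–5 binning
  via per-item noise for youth frequency items, clipped rounding for GPAQ
  days, non-negative rounding for counts and minutes). The generator
  deliberately mirrors what the mixed model assumes — latent linearity,
  Gaussian cluster effects — rather than real-world response processes;
* epoch streams: 7 days from a Monday, device worn 07:00–20:00 (13 h, so
  all days are valid by construction), overnight zeros forming non-wear
  runs, low sub-cutpoint background counts while worn, and
  Poisson-injected supra-cutpoint epochs whose daily rate rises linearly
  in the participant's percent score (children get additional bouts inside
  the reported 16:00–18:00 neighborhood window).

Randomness uses numpy Generator substreams keyed by (seed, component) for
the vectorized tabular draws and (seed, component, participant index) for
epoch streams, so studies are byte-reproducible for a fixed seed.

**What passing tests show — and don't.** Recovery and type-I results on
this generator certify the pipeline's statistical correctness under the
model's own assumptions. Real audit data violate them in known ways:
ordinal outcomes are not latent-Gaussian, item responses are spatially
correlated within routes and neighborhoods beyond the binary stratum,
wear patterns are irregular, and activity is not a Poisson overlay. The
experiments validate the software, not the instrument.

## Experiment sizes

Repeated-simulation experiments use a scaled configuration — 200
participants per age group in 50 block groups, accelerometer streams off,
200 replicates — sized so Monte-Carlo error on the recovered effect is a
small fraction of the 5% bias criterion while the full suite stays quick
to run. Recovery targets the adult leisure outcome (minutes/day,
β_score = 0.6 min per percent point, σ = 12, τ = 4): a continuous scale
whose rounding is bias-neutral, so the estimate isolates pipeline bias
rather than ordinal-binning attenuation. The type-I experiment re-runs the
same configuration with β_score = 0. Observed behaviour (200 reps):
relative bias well under 1%, 95% CI coverage ≈ 0.97, null rejection rate
≈ 0.05–0.08 — the mild liberality expected of normal-approximation Wald
tests at 50 clusters, within three Monte-Carlo standard errors of α.

## Known limitations

* Per-item score ranges and item observation levels are assumptions where
  the instrument publishes only aggregate facts; both are configurable.
* Normal-approximation p-values are slightly liberal at small cluster
  counts; with few block groups, prefer a larger α-robust design or treat
  borderline p-values cautiously.
* Youth cut-point defaults come from a published regression, not from the
  exact thresholds any particular study used.
* The CSV formats are deliberately plain (no device-native AGD parsing,
  no GPS route geometry); proprietary exports must be converted upstream.
* Ordinal outcomes are modeled linearly throughout, as the validation
  design does; effect magnitudes on 0–5 scales are therefore
  scale-dependent and not comparable across age groups.
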