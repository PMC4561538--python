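# mapsmini

Scoring and validation pipeline for **MAPS-Mini**, the 15-item Microscale
Audit of Pedestrian Streetscapes. The package is for built-environment and
physical-activity researchers (and the practitioners who adopt the
instrument) who need to turn street-level audit observations into
participant scores, link them to survey- and accelerometer-derived physical
activity, and test score–activity associations with cluster-adjusted mixed
models. Because audit studies rarely deposit raw cohorts, the package ships
a synthetic-study generator with the same statistical structure, so every
stage of the pipeline is testable end to end.

## What it computes

**Audit scores.** An observer walks a 0.25-mile route from a residence
toward the nearest non-residential destination and records 15 items —
sidewalks, buffers, street lights, benches, crosswalks, curb cuts, crossing
signals, transit stops, commercial use, parks, trees, trip hazards, graffiti,
building maintenance, bicycle facilities — each scored 0–1 or 0–1–2.
Segment-level items are averaged over the street block faces on the route
and crossing-level items over its intersections. With item score
$x_i \in [0, \max_i]$, the participant's total and percent-of-maximum are

$$T = \sum_{i \in \text{total}} x_i, \qquad
  P = 100 \cdot \frac{T}{\sum_{i \in \text{total}} \max_i}.$$

Items with no observations on a route (e.g. crossing items on a
crossing-free route) are dropped from both numerator and denominator, so
$P$ stays comparable across routes. The bicycle item grades protection
from cars: no facility or sharrows → 0, painted lane → 1, physical
protection → 2.

**Physical-activity outcomes.** Active transport and leisure/neighborhood
activity come from age-appropriate surveys (mean 0–5 destination
frequencies for youth, GPAQ items for adults, CHAMPS items for older
adults). Objective MVPA comes from epoch-level accelerometer counts:
non-wear is any run of consecutive zero-count epochs ≥ 20/30/45 min
(children/adolescents/older adults), a valid day has ≥ 10 h wear, and MVPA
minutes are wear epochs at or above a Freedson counts-per-minute cut point,
optionally restricted to non-school hours (weekdays 3–11 PM plus weekends)
or to reported neighborhood time intervals.

**Validation models.** For every item (and the total score), outcome class,
and age group, a linear mixed model

$$y_{jk} = \beta_0 + \beta_1\, x_{jk} + \boldsymbol{\gamma}' \mathbf{z}_{jk}
  + b_k + \varepsilon_{jk}, \qquad b_k \sim N(0, \tau^2)$$

is fit by REML, with covariates $\mathbf{z}$ (age, sex, education,
race/ethnicity, macrolevel walkability, plus mobility function for older
adults) and a random intercept $b_k$ per census block group. The package
reports the predictor's Wald $t$ and $p$, counts significant associations
per outcome class, and contrasts unadjusted outcome means across
percent-of-max quintiles.

## Worked example

```bash
cat > config.yaml <<'EOF'
seed: 7
data_dir: study
output_dir: results
alpha: 0.05
sim:
  n_block_groups: 12
  participants: {child: 50, adolescent: 50, adult: 50, older_adult: 50}
  simulate_accel: false
EOF
mapsmini simulate -c config.yaml
mapsmini score -c config.yaml
mapsmini validate -c config.yaml
```

prints

```
wrote synthetic study (200 participants) to study
INFO mapsmini: scored 200 routes (47 with missing-item renormalization)
wrote results/participant_scores.csv
wrote association matrices to results (44 cell(s) failed or lacked data)
```

Forty-seven of the 200 simulated routes had no crossings, so their percent
score was renormalized to the nine observable items. With
`simulate_accel: false` the MVPA outcome is absent, which is why the 44
accelerometer cells for the wearing groups report "lacked data" (run
`mapsmini accel` on a bundle simulated with `simulate_accel: true` to fill
them); adult MVPA cells are structurally absent because parents did not
wear devices. `results/association_summary.csv` then holds, per outcome
class, the significant-association count over the available tests:

```
outcome_class,n_significant,n_tests,percent_significant
transport,3,59,5.1
leisure,7,59,11.9
```

(59, not 60, because the commercial item is unavailable for older adults.)
`results/quintile_means.csv` gives the unadjusted outcome mean per
percent-of-max quintile with the top-minus-bottom contrast, e.g. for
adolescent transport a Q1 mean of 1.11 and Q5 mean of 1.46 times/week, a
difference of 0.35 (31.1%). At this small demo size few cells reach
significance; the recovery experiments in `mapsmini.synthetic` show the
model's behaviour at study-like sizes.

The same stages are callable as a library — `simulate_study`,
`score_dataset`, `detect_nonwear`/`summarize_days`,
`assemble_analysis_table`, `run_association_matrix` — see the module
docstrings.

## Layout

| module | role |
| --- | --- |
| `mapsmini.audit` | item catalog, route/segment/crossing observations, CSV I/O, validation |
| `mapsmini.scoring` | item aggregation, total score, percent-of-max, quintiles |
| `mapsmini.accelerometry` | non-wear detection, valid days, MVPA minutes, clock/location filters |
| `mapsmini.outcomes` | survey outcome scoring, covariates, analysis-table assembly |
| `mapsmini.validation` | mixed regressions, association matrix, significance counts, quintile contrasts |
| `mapsmini.synthetic` | synthetic study generator, recovery experiments |
| `mapsmini.cli` | `mapsmini simulate / score / accel / validate` |

Methodological details, parameter defaults, and known limitations are in
[`docs/methods.md`](docs/methods.md).
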