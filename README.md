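# circabench

**Is a time-of-day effect a circadian rhythm, or just who shows up?**

Always-available online studies collect data around the clock, which makes
it tempting to read any time-of-day pattern in the outcome as a circadian
rhythm. But nobody assigns participants to a time of day: morning
respondents and midnight respondents are different people, so a
time-of-day pattern can be produced entirely by *selection* — groups with
different outcome levels participating at different hours. `circabench`
implements the inferential toolkit for separating the two stories on
cross-sectional data, built around single-component 24-h cosinor
regression. It is aimed at researchers analysing large observational
datasets with timestamps (demonstration websites, social media, crowd
work) and at methodologists studying selection artefacts.

## The model

The rhythm model is the single-component cosinor with fixed 24-h period,

    y_i = M + A·cos(2π(t_i − φ)/24) + e_i,

fitted through its linear decomposition

    y_i = M + β_s·sin(2πt_i/24) + β_c·cos(2πt_i/24) + e_i

by ordinary least squares, where *t_i* is local clock time in hours, *M*
is the mesor (midline), *A* = √(β_s² + β_c²) the amplitude and
φ = (24/2π)·atan2(β_s, β_c) the acrophase — the clock time of the fitted
peak. Rhythm strength is the percentage of variance explained by the
sine/cosine pair, tested with the joint F-statistic
F(2, n−3) = (r²/2)/((1−r²)/(n−3)).

The analysis proceeds in three parts:

1. **Replication** — covariates are never entered into the cosinor;
   instead the outcome is first residualized on dummy codes for every
   level of each demographic covariate plus linear and quadratic
   study-day terms (detrending), and the cosinor is fitted to the
   residuals.
2. **Convergent validity** — if the rhythm is circadian it should peak
   earlier during daylight saving time, earlier among women, and earlier
   among older adults. Moderation is tested by adding sine×moderator and
   cosine×moderator interactions and jointly testing the pair; the age
   analysis additionally fits one cosinor per year of age and regresses
   the per-year acrophases on age, weighted by the contributing counts.
3. **Selection benchmark** — the same cosinor machinery is applied to
   variables that *cannot* oscillate within a person over a day (age;
   gender via logistic response residuals). Any "rhythm" they show is
   pure selection, and its variance explained benchmarks how much rhythm
   the outcome would need to exceed before a circadian reading is
   warranted.

Timestamps arrive on the server clock and are converted to local time via
an explicit per-region offset table (counties straddling two time zones
are coded half-way, i.e. a 0.5-h offset); days containing a DST
transition are excluded.

A seeded synthetic-data generator produces participant tables with the
same schema under named scenarios (`null`, `circadian`, `selection_only`,
`mixed`, `gender_phase_shift`, `age_phase_gradient`, `dst_phase_shift`),
so every stage is testable end to end without any external data.

## Worked example

```python
from circabench.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(preset="circadian", n=200_000, seed=1))
p1 = report["part1"]["adjusted"]
print(p1["acrophase_hhmm"], round(p1["r2_pct"], 3), round(p1["f_stat"], 1))
```

prints

```
21:07 0.087 86.4
```

The `circadian` scenario injects a rhythm carrying 0.08% of residual
variance peaking at 21.17 h (≈ 9:10 pm) into an evening-heavy
participation stream of 200,000 synthetic participants; the pipeline —
time-zone conversion, DST-day exclusion, in-group recoding, demographic
residualization, cosinor — recovers a peak at 21:07 with r² = 0.087%,
F(2, 198962) = 86.4. In the same report, gender moderation is
non-significant (p = 0.84; no shift was injected) and the fixed-variable
benchmarks for age and gender are at the sampling noise floor
(r² ≤ 0.0007%), i.e. no selection is detected — the configuration under
which a circadian interpretation survives. Running the
`selection_only` preset instead produces a significant raw-outcome
rhythm that collapses under adjustment while the age benchmark stays an
order of magnitude above it: the signature of selection.

The same pipeline runs from a shell:

```bash
circabench simulate --preset selection_only --n 100000 --seed 1 --out data.csv
circabench run --preset circadian --n 200000 --seed 1 --out results/
```

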