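# Methods

## Model and estimation

The core model is the single-component cosinor with the period fixed at
24 h. It is estimated through the sine/cosine linearization by ordinary
least squares (`numpy.linalg.lstsq` on the [1, sin, cos] design), which
is the exact maximum-likelihood fit under Gaussian errors. Amplitude and
acrophase are recovered as A = √(β_s² + β_c²) and
φ = (24/2π)·atan2(β_s, β_c) mod 24; the two-argument arctangent places
the peak in the correct quadrant, so a pure cosine peaks at 00:00 and a
pure sine at 06:00. Rhythm strength is reported as percent variance
explained, with the joint F-test of the two trigonometric coefficients,
F(2, n−3) = (r²/2)/((1−r²)/(n−3)); p-values are upper-tail areas of the
F distribution and no multiple-testing correction is applied.

Covariates never enter the cosinor itself. Continuous outcomes are
residualized by OLS on an intercept, one indicator per non-reference
level of each categorical covariate, and linear plus quadratic
study-day terms; binary outcomes (the gender benchmark) are residualized
by a maximum-likelihood logit fitted by IRLS (statsmodels GLM/Binomial),
taking **response residuals** (observed 0/1 minus fitted probability) so
the variance-explained computation downstream uses the same sums-of-
squares logic as the continuous case. Study day is days since the
earliest record, centered and rescaled to [−1, 1] before squaring, which
keeps the quadratic term well conditioned; residuals are invariant to
this affine choice and to the choice of reference level.

Moderation of the rhythm adds the moderator main effect(s) plus
sine×moderator and cosine×moderator columns, and tests the interaction
block with a Wald F-test computed from the nested sums of squares (2
numerator df for a binary or continuous moderator, 2(L−1) for an L-level
categorical one). Per-level rhythms are refitted within level; for
continuous moderators the implied coefficients at stated reference
values are reported. Acrophase differences are wrapped into (−12, +12] h
before reporting.

The per-age analysis fits one cosinor per year of age and regresses the
saved acrophases on age by weighted least squares with weights equal to
the contributing observation counts, reporting the slope in minutes per
year. Acrophases are clock times, so before the linear fit each stratum
acrophase is mapped onto the 24-h branch nearest the circular mean
across strata; without this, a rhythm peaking near midnight would
produce artificial 24-h jumps in the regression. Strata with fewer than
50 observations (configurable) are dropped with a warning, and the
regression requires at least three strata.

The selection benchmark residualizes a fixed variable (default: age
continuously, gender by logit) on the remaining demographic covariates
plus detrending, fits the cosinor to those residuals, and reports each
benchmark's variance explained as a ratio to the outcome's. Ratios are
scale invariant and rounded to 2 dp in reports; a zero outcome r² flags
the ratio as infinite rather than failing.

## Time handling

Server timestamps are converted to local wall-clock time with an
explicit per-region table: a signed offset in hours (half-integer
offsets encode counties straddling two zones, coded half-way between
them) and, for DST-observing regions, intervals in local standard time
during which one hour is added. The US rules are generated
programmatically (2007+: second Sunday of March 02:00 to first Sunday of
November 02:00; 2006: first Sunday of April to last Sunday of October)
rather than taken from an OS timezone database, so runs are hermetic and
reproducible; custom tables can be loaded from CSV. Records whose local
date is a DST transition date in their zone are excluded, because wall
clock time is skipped or repeated on those days. Clock time is stored as
decimal hours on the circle [0, 24); half-hour binning exists only in
reporting.

## Synthetic data generator

The generator emulates a large always-online study, cross-sectional with
one record per participant:

* **Age** 18–89 with per-year probability ∝ exp(−(age−18)/12), giving a
  young-skewed distribution with ~84% of participants aged 40 or less.
* **Gender** 60% female / 40% male; **race** 71% White / 13% Black /
  16% other, with race-specific mean in-group preference (0.40 / 0.15 /
  0.33 on the recoded scale) and residual noise SD 0.43.
* **Participation time** by inverse-CDF sampling from a 24-bin circular
  histogram, evening-heavy with a pre-dawn trough (peak ≈ 21:00, trough
  ≈ 04:00, ratio ≈ 7:1). Selection mechanisms shift this density per
  race group, for women, per year of age, or via a latent standard
  normal "chronotype" that can also enter the outcome.
* **Rhythm** as an additive cosine whose amplitude is derived from a
  target percent-variance-explained: the variance of the unit cosine is
  computed under the actual (non-uniform) sampling density by numerical
  integration, and A = σ·√(f/(v(1−f))) solves for the requested
  fraction f. Phase modifiers move the acrophase earlier for women,
  earlier during DST, and later per year of age, matching the sign
  conventions of the chronobiology literature.
* **Timestamps** are assembled in local wall time over a 365-day study
  window starting 2013-01-01, then inverted to the server clock through
  the same zone table the pipeline uses, so the conversion round-trips.

Scenario presets fix the study conditions: the weak-rhythm scenario uses
r² = 0.08% peaking at 21.17 h; the gender scenario shifts women's peak
78 min earlier; the age scenario delays the peak 3 min/year over a
uniform 18–40 age distribution; the DST scenario moves the peak 30 min
earlier while DST is in effect. The moderation and gradient presets use
clearly detectable rhythms (r² of 4% and 15% respectively): these
scenarios validate the *phase geometry* of the estimators — that a
constructed shift is recovered with the right size and sign — rather
than their power at trace effect sizes, which is governed by the
weak-rhythm scenario.

What the generator does **not** emulate: trial-level IAT latencies (it
starts from person-level scores), geographic or seasonal structure
beyond the time-zone table, day-of-week cycles, repeat participation,
missing-data mechanisms, or secular drift in the outcome (drift handling
is exercised by injecting trends in tests). Passing tests therefore
demonstrate the estimators' correctness and calibration under the stated
generative structure, not robustness to every feature of real
participation data.

## Numerical choices and degenerate inputs

* Cosinor fits require n ≥ 10 and at least three distinct clock times;
  constant outcomes return amplitude 0, r² 0, F 0 (acrophase is then
  undefined and raises if requested).
* Aliased (rank-deficient) adjustment columns are dropped with a
  warning, keeping earlier columns; perfect separation in the logit is
  reported as an error naming the covariates.
* Rows missing the outcome, a covariate or the timestamp fields are
  listwise-deleted per analysis with logged counts; the pipeline report
  reconciles input = retained + sum of exclusions.
* Moderator levels with fewer than 100 observations (configurable) are
  dropped with a warning; a moderator constant after dropping is an
  error.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; a fixed seed reproduces tables
  bit-identically.

## Problem sizes

The validation suite and the reproduction script run the weak-rhythm and
gender scenarios at n = 200,000, the selection scenario at n = 500,000,
the age gradient at n = 115,000 (≈5,000 per year of age), and the null
calibration over 1,000 replicates of n = 5,000 — sizes at which each
effect's estimator is comfortably identified while the whole suite runs
on a laptop in a few minutes. At the weak-rhythm effect size (r² =
0.08%, n = 200,000) the asymptotic standard error of the acrophase is
itself ≈ 18–23 min, so single-run recovery within ±20 min is expected
but not guaranteed on every seed; the reproduction script reports the
recovered value as computed.

## Known limitations

* The single-component, fixed-24-h cosinor captures only sinusoidal
  patterns; multi-component or non-24-h rhythms are out of scope.
* The continuous-moderator acrophase shift is a linear-in-coefficients
  approximation and is accurate for phase differences well below a
  quarter cycle.
* Benchmark comparisons are descriptive (ratios), with no formal test
  between r² values of different models.
* Real-data headline values from the motivating literature depend on a
  proprietary-scale dataset (~1.28M records) and are not reproduced
  here; the package validates the machinery on synthetic data with
  known truth.
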