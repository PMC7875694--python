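# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohort, the numerical choices, and the limits of
what the test suite establishes.

## Sensor model and cleaning

Events are durative records `(participant, sensor, start, duration)` for
three sensors: calls, battery charging, screen unlocks. Two cleaning
rules run before any feature is computed:

- battery events with duration **strictly below 10 s** are dropped
  (spurious connect/disconnect glitches; a 10 s event survives);
- screen sessions **strictly above 2 h** are dropped (continuous use such
  as navigation; a 2 h session survives).

Both thresholds are configurable; the strict reading of
"shorter/longer than" is the default because the boundary events carry no
evidence of being artefacts. Filters are idempotent, never reorder
events, and report the removed fraction. Notification-induced screen-on
events are assumed excluded by the collector; an optional boolean column
in the interchange CSV drops flagged rows when present. Timestamps are
stored timezone-aware and hour-of-day binning uses the timezone the
timestamps carry.

## Features

Fifteen slots, five per sensor. Windowing conventions, chosen to keep
rate/duration statistics event-based and occupancy occupancy-based:

- an event belongs to a window for `Freq`, `Mean`, `SD`, `Ent` iff its
  **start** lies in the half-open window, with the full (unclipped)
  duration entering the moments;
- `Use` clips each event's duration to the window, so `Use` is additive
  over window partitions;
- entropy bins starts by local clock hour, natural log (maximum ln 24 ≈
  3.178); the log base is configurable. Durative events are not smeared
  across bins — entropy is an occurrence statistic.

Missing-data policy: `Use` and `Freq` are genuinely 0 for an event-free
window; `Mean`, `SD`, `Ent` are missing (NaN) there because their
defining sets are empty. `SD` of a single event is 0.

Trait-level analysis uses one window spanning the full observation span;
daily analysis uses the 24 h window ending at each morning assessment
(08:00 by default). Evening and previous-day outcomes reuse the
morning-anchored window; irregular assessment times may produce
overlapping windows and are accepted as-is.

## Trait pipeline

Correlations are pairwise Pearson over complete cases. The regression
stage interprets the "penalty 0.05" as the Lasso regularization strength
applied to column-standardized predictors and a centered response, the
same value for all nine trait outcomes; the active set is refit by OLS
and reported with standardized coefficients, F(k, n−k−1) and adjusted R².
These p values are **post-selection**: measured on null synthetic
cohorts, the overall F rejects at ~33% rather than 5%, so the report logs
a warning and the package treats them as descriptive.

The confirmatory read-out is leave-one-subject-out prediction with a
linear SVR (C = 1, ε = 0.1 — unstated in the design, fixed as defaults
and configurable). Standardization statistics and, by default, a per-fold
re-run of the Lasso selection are learned on the training fold only; a
corruption test verifies the held-out participant's outcome can never
influence their own prediction. Under the null, LOSO predictions carry
the well-known negative correlation with the held-out truth (measured
mean r ≈ −0.05 at n = 26), which inflates a two-sided test to ~15%; the
**one-sided (positive) test is calibrated** (measured 5.7% on 540 null
models) and is what the acceptance suite checks as the type-I rate.

## Daily-state pipeline

Per outcome: a Gaussian GEE with exchangeable working correlation
clustered by participant (independence available by config). The report
carries (a) the in-sample Pearson r between fitted and observed values
with its naive p — the presentation-style summary — and (b) a joint test
of the 15 feature coefficients using the robust covariance with a
Hotelling-type small-sample F reference, F = W(m−k)/(k(m−1)) on
(k, m−k) df for m clusters. The naive chi-square Wald rejects ~70% under
the null at m = 26, k = 15; the F correction measures ~6%. The estimated
exchangeable parameter is reported as the within-group correlation.
A zero-residual outcome (exact linear function of the features)
degenerates the GEE scale estimate; the fit falls back to OLS, which is
the identical solution, with the working correlation reported as 0.

Classification binarizes each outcome at the **pooled** median (per-
individual medians available by config), labels 1 strictly above, and
runs logistic regression under LOSO with training-fold standardization;
single-class training folds fall back to the majority class with a
warning. Accuracies are aggregated per held-out individual.

## Task simulators

**Go/no-go**: 75 trials; cue orientation uniform, stimulus-onset
asynchrony uniform over {100, 200, 300, 400, 500, 750} ms, target
consistent with the cue with probability 0.70 (horizontal signals go).
Agents omit go responses and commit on no-go targets at per-trial lapse
rates; latencies are normal truncated to the 500 ms response window, and
only responded go trials enter the latency mean. Commission is defined
conventionally (response on no-go) — the metric table's inverted
"go/no-go error" wording is treated as a labelling slip.

**Delay discounting**: adjusting-amount staircase of five choices against
a fixed delayed reward; the immediate offer starts at half the delayed
amount and steps halve each trial (delayed/4 … /32, with a final
half-step). A hyperbolic agent prefers the immediate amount when it
exceeds delayed/(1 + k·delay), softened by logistic choice noise. For a
noiseless agent the staircase is an exact bisection: the indifference
estimate is within the final half-step of the true indifference point and
is monotone in k. The raw fraction of immediate choices (present bias)
is **not** monotone in k for noiseless agents — it counts descent steps
of a binary-search path — but its expectation under choice noise is; the
tests assert the true versions of both properties.

**Balloon task**: 15 balloons, explosion point uniform on
{1..max_pumps}; the agent intends a noisy number of pumps around its
target and loses the trial's gains if the balloon pops first. For a fixed
t-pump policy the expected per-trial gain is pay·t·(M−t)/M, used as the
analytic oracle. Defaults (M = 12, pay = 3.7, target ≈ 4.5) put session
means near the design's descriptive anchors (≈3.9 pumps, ≈10.3 gains).

All simulators are bit-reproducible given a seeded generator.

## Synthetic cohort generator

Defaults encode the study conditions: 26 participants, 21 days, morning
assessments at 08:00, outcomes and traits matched to the design's
descriptive tables.

**Traits.** A Gaussian copula with exchangeable correlation 0.3 couples
nine questionnaire scores; each marginal is a normal truncated to the
item range [1, 4] whose pre-truncation parameters are solved numerically
so the post-truncation mean and SD equal the descriptive targets exactly.
(Naive truncation-by-resampling biased means by up to +0.13.)

**Streams.** Per participant and sensor, a rate and a mean duration are
drawn jointly lognormal. The log-scale correlation between them is
negative (battery −0.74, call −0.33, screen −0.96), which is what makes
the three descriptives — occupancy, rate, and mean duration — mutually
consistent: the descriptive table is a set of means of ratios, not a
consistent triple of population moments. Occurrences then follow an
inhomogeneous Poisson process with hourly intensities proportional to a
circadian template raised to a per-participant exponent γ (γ = 0 uniform,
entropy ln 24; larger γ concentrates activity). γ defaults (battery 2.10,
call 2.11, screen 1.19) were calibrated once by bisection so cohort
plug-in entropies land on the descriptive targets after finite-sample
bias at realistic event counts; γ spreads approximate the entropy SDs.
Day-to-day rate jitter is lognormal (σ = 0.15). Contaminant events
(sub-10 s battery, > 2 h screen) are injected so the filters remove
roughly the fractions the cleaning step is known to remove (16.5% /
0.4%).

**Planted effects.** A trait→feature link with strength ρ plants a
correlation between the trait z-score and the participant-level log-rate
(`*_Freq`), log-duration (`*_Use`), or log-γ (`*_Ent`, sign inverted and
amplified by a calibrated attenuation constant, since count noise dilutes
the γ signal in observed entropy: battery 0.77, call 0.90, screen 0.98).
Default links give sensation seeking +0.55 battery frequency, +0.55
screen use, −0.65 call entropy — magnitudes chosen so the three-predictor
sensation model has population R² ≈ 0.62, the strength the design's
regression table reports. One effect is emergent rather than planted:
battery entropy correlates ~0.3 with sensation seeking purely because the
frequency link changes event counts and hence plug-in entropy bias.

**Daily outcomes.** Each EMA/affect outcome is mean + SD × (feature link
+ random intercept + noise), clipped to its response range. The link term
weights each linked feature's daily z-score plus an extra weight (boost
1.5) on its participant-mean component: day-level outcomes track stable
usage patterns more than daily wobble, which is what produces the joint
pattern of moderate GEE r alongside high LOSO classification accuracy.
Residual variance splits by an ICC of 0.5 (assumption; flagged in
provenance). The three intentional–impulsive items carry **no feature
link** and a higher ICC (0.75), mirroring their high reported
within-person stability; they are the designed null. Task metrics come
from agents whose parameters derive from trait z-scores (discount rate
increasing in overall impulsivity, pump target in sensation seeking) with
day-level modulation by the day's screen frequency. The go/no-go lapse
base rate is 0.0125 on the logit scale so that, after logit-normal
spread, the observed mean error rate centres on the 0.02 anchor.

**Seeding.** A master seed spawns per-participant/per-sensor/per-day
substreams via seed sequences, so adding a participant or day never
perturbs existing data; bundles are byte-identical under a fixed seed.

## What the tests show — and what they don't

The generator emulates circadian structure, heavy-tailed durations,
between-person heterogeneity, planted effect signs, contamination, and a
designed null outcome. It does **not** emulate weekday/weekend structure,
app-level usage microstructure, missing-not-at-random compliance, or
measurement reactivity. Passing tests therefore establish that the
pipelines are correct and calibrated under the stated generative model at
the study's scale — not that the substantive findings generalize to real
cohorts. Parameter-recovery results (sign recovery ≥ 90% at n = 26, GEE
CI coverage ≈ 95%, ICC recovered within ±0.1) are statements about the
procedures under these conditions.

## Problem sizes

The suite runs its heavy checks at the study's own scale: 100 cohort
replicates (26 × 21 days) for sign recovery, 40 for the null type-I rate,
200 daily-outcome replicates for GEE coverage, 200 go/no-go sessions for
the cue-validity check; the full suite completes in a few minutes on one
CPU.
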