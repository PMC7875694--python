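# mpulse

Passive smartphone sensing for digital phenotyping of impulsivity: feature
extraction from phone-sensor event streams, trait- and state-level
prediction pipelines, simulators for three mobile behavioural tasks, and a
synthetic cohort generator that makes the whole analysis testable end to
end without any participant data.

## Who this is for

Researchers in mobile sensing / digital phenotyping who want a tested,
reusable implementation of a common study design: a small cohort (tens of
participants) carries a sensing app for a few weeks; the app logs **call
events, battery-charging sessions, and screen-unlock sessions**; daily
self-reports (EMA semantic differentials, photographic affect) and brief
mobile tasks (balloon risk task, go/no-go, delay discounting) provide the
outcomes; baseline questionnaires (BIS-15, UPPS) provide stable trait
scores.

## The model

**Features.** For each sensor and time window, five statistics form a
15-slot vector `{battery,call,screen}_{Use,Freq,Mean,SD,Ent}`:

- `Use` — hours of event time per observed hour,
- `Freq` — events per observed hour,
- `Mean`, `SD` — moments of event durations (hours),
- `Ent` — Shannon entropy (nats) of event start times over the 24
  hour-of-day bins, H = −Σₕ pₕ ln pₕ ∈ [0, ln 24]; low entropy means
  temporally concentrated usage.

Cleaning first drops battery events shorter than 10 s (connector
glitches) and screen sessions longer than 2 h (navigation/video, not
checking).

**Trait level** (one vector per participant over the whole study):
Pearson correlations against each questionnaire scale; Lasso selection
(penalty 0.05 on standardized predictors) followed by an OLS refit
reporting standardized β, F(k, n−k−1) and adjusted R²; and
leave-one-subject-out (LOSO) linear support-vector regression scored by
MAE and the Pearson r between predicted and true scores. The refit p
values are post-selection and optimistic; the LOSO block is the honest
out-of-sample check.

**Daily level** (one vector per participant-day from the 24 h window
before the morning assessment): a Gaussian GEE with exchangeable working
correlation clustered by participant (reporting the in-sample fitted-vs-
observed Pearson r, the estimated within-group correlation, and a
small-sample Hotelling-type joint F test of the feature coefficients), and
a median-split binary classification (label 1 iff strictly above the
pooled median) with logistic regression under LOSO, reporting per-
individual accuracies.

**Synthetic cohort.** Event occurrences follow inhomogeneous Poisson
processes whose hourly intensities temper a circadian template by a
per-participant concentration exponent (the entropy dial); durations are
lognormal; rate and mean duration are negatively correlated across
participants so occupancy, rate and duration descriptives are matched
simultaneously. Trait→feature effects and daily feature→outcome links are
planted with configurable strength; task metrics come from parameterized
agents (hyperbolic discounter on the staircase, lapse-rate responder on
go/no-go, noisy-target pumper on the balloon task).

## Worked example

```python
from mpulse.synth import SyntheticCohortConfig, generate_bundle
from mpulse.traits import run_trait_battery
from mpulse.state import run_state_battery

bundle = generate_bundle(SyntheticCohortConfig(seed=3))
trait_report = run_trait_battery(bundle.trait_feature_table, bundle.traits)
state_report = run_state_battery(
    bundle.daily_features.reset_index(drop=True), bundle.daily)

sens = trait_report["regression"]["upps_sensation"]
print(sens["df"], round(sens["adj_r_squared"], 2))
loso = trait_report["loso"]["upps_sensation"]
print(round(loso["mae"], 3), round(loso["pearson_r"], 2))
for o in ("am_thrill_seeking", "prev_impulsive"):
    r = state_report[o]
    print(o, round(r["pearson_r"], 2), round(r["wald_p"], 3),
          round(r["accuracy_mean"], 2))
```

prints

```
[6, 19] 0.91
0.251 0.88
am_thrill_seeking 0.61 0.0 0.55
prev_impulsive 0.2 0.925 0.43
```

Reading this: on the default 26-participant, 21-day synthetic cohort the
sensation-seeking model selects six features and explains most of the
trait variance (the planted effects are strong and post-selection R² is
optimistic by construction); LOSO prediction confirms real out-of-sample
signal (MAE 0.25 scale points, r = 0.88). On the daily level the
thrill-seeking differential — which the generator links to screen
features — yields a significant GEE model (joint test p < .001), while
the previous-day impulsive item — generated with **no** feature link —
does not (p = .93) despite its high within-person stability. That
dissociation (behavioural and affect outcomes predictable, face-valid
impulsivity self-reports not) is the qualitative pattern the default
configuration is built to reproduce.

The same pipeline is scriptable from the shell:

```bash
mpulse synth --seed 3 --out bundle/
mpulse ingest --sensor battery --in bundle/sensors/P001_battery.csv --out clean.csv
mpulse run-all --seed 3 --out reports/
```

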