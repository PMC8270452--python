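# disorient

Statistical detection of collective **disorientation** in opinion-polarity
time series built from labelled social-media posts.

When a contested health topic — here, vaccination — is fought over in
public by political actors, people exposed to contradictory messages may
stop holding stable opinions. This package operationalises that idea for a
stream of posts labelled **favourable (F)**, **contrary (C)** or
**undecided (U)** (plus out-of-context posts that are discarded):

* **Short-term disorientation** — days on which the observed polarity
  count vector (n_F, n_C, n_U) is incompatible with an "average opinion"
  null. Three tests are provided, all at day resolution:
  * *basic multinomial*: day t's counts ~ Multinomial(N_t, π) with π the
    pooled whole-period proportions; the p-value is the exact conditional
    one, p = Σ { P(x) : P(x) ≤ P(observed) } over all three-part
    compositions of N_t (full enumeration up to a configurable cap,
    seeded Monte Carlo above it);
  * *running multinomial*: the same test with π rebuilt for every day from
    the mean daily proportions of the preceding 15 days, sensitive to fast
    shifts rather than slow drift;
  * *running variance*: T = (w−1)s²_w/σ₀² ~ χ²(w−1) comparing the trailing
    15-day variance of the favourable share with the whole-period variance
    σ₀², two-sided (turbulent *and* frozen windows reject).

  The evidence of disorientation is the excess of rejection days over the
  chance expectation α × (tested days) — about 18 days per year at
  α = 0.05 — so no multiplicity adjustment is applied by design.

* **Long-term disorientation** — slow waves in the smoothed polarity
  proportions. Smoothing uses a discrete beta kernel: the weights at day x
  are a Beta(x/(Th)+1, (T−x)/(Th)+1) density evaluated on the rescaled day
  grid j/T and renormalised, so no weight ever leaves the observed
  interval (no boundary bias) and h → 0 recovers the identity. The
  bandwidth is chosen by leave-one-out cross-validation and the smoothed
  favourable share is summarised by stepwise polynomial least squares
  (smallest degree whose successor gains < 0.01 in R²).

* **Annotation quality** — Fleiss' kappa and raw pairwise accuracy with a
  Clopper–Pearson interval for multi-rater labelling campaigns.

* **Synthetic scenarios** — a fully seeded generator for labelled post
  streams with a baseline opinion split, negative-binomial daily volumes
  with spike days, short additive opinion shocks, a logit-quadratic
  year-scale trend, out-of-context chatter, duplicates and noisy
  annotators, so the whole pipeline is testable without any data
  download.

## Worked example

The `analysis/` scripts run the full study on a simulated year
(`python analysis/01_simulate_scenario.py` … `05_calibration_power.py`).
Equivalently, from Python:

```python
from disorient import (demo_scenario, generate_series, basic_daily_test,
                       running_daily_test, rejection_summary)

series, truth = generate_series(demo_scenario(20180101), seed=20180101)
summary = rejection_summary(basic_daily_test(series, seed=20180101))
print(summary.as_frame())
```

On the demo scenario (three volume spikes, three short opinion shocks, a
rise-then-fall favourable trend) the pipeline prints:

```
pooled proportions: F=69.8% (CI 69.5%-70.1%), C=16.4%, U=13.8%
hesitant share (C+U): 30.2%
   basic: 61 days at alpha=0.1 (expected 36.5), 38 days at alpha=0.05 (expected 18.2), 15 days at alpha=0.01 (expected 3.6)
 running: 49 days at alpha=0.1 (expected 35.0), 27 days at alpha=0.05 (expected 17.5), 10 days at alpha=0.01 (expected 3.5)
variance: 124 days at alpha=0.1 (expected 35.1), 75 days at alpha=0.05 (expected 17.6), 26 days at alpha=0.01 (expected 3.5)
parabolic component peaks at day index 121 (R^2 0.746)
```

Reading: the pooled split estimates the population polarity (C+U is the
*hesitant* share); every test rejects on far more days than chance would
give, i.e. the injected shocks and trend produce exactly the excess of
"incompatible" days the method is built to flag; and the degree-2
component of the trend fit localises the true opinion peak (day 116 in
the generating trend) to day 121.

A `disorient` command-line tool exposes the same stages
(`disorient simulate | ingest | test | smooth | run`); see `--help`.

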