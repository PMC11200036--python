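# sleepjitai

A tested pipeline for analysing a **sleep just-in-time adaptive intervention
(JITAI)** evaluated by a **microrandomized trial (MRT)**, from raw wrist
actigraphy to effect estimates.  It is aimed at researchers in digital
health / biostatistics who want to reproduce, extend, or power this class of
two-study design:

* **Observational phase** ("study 1"): participants wear a wristband
  accelerometer recording 1-minute zero-crossing counts and answer
  smartphone EMA prompts.  The pipeline scores each minute sleep/wake
  (Cole-Kripke weighting with Webster rescoring), finds each night's sleep
  interval as the square wave best matching the labels, and summarises each
  participant by the intraindividual mean (IIM) and variability (IIV) of
  sleep hours, midpoint of sleep (circular statistics), and sleep
  efficiency.  Ward clustering on the standardized six-feature vector
  dichotomizes the cohort into a stable group A and an unstable group B,
  and linear mixed models relate momentary symptoms to IIV.
* **Intervention phase** ("study 2"): each day, feedback on last night's
  sleep relative to the participant's own average is push-delivered with
  probability 0.5 (microrandomization).  Proximal effects are estimated by
  a linear mixed model; a hierarchical Bayesian model estimates the
  day-varying effect and its mediated ("cascading") effect on next-morning
  symptoms; distal effects use 2x2 mixed-effect ANOVA with Tukey-adjusted
  contrasts.

Because raw trial data of this kind are rarely shareable, the package
includes a first-class synthetic-cohort generator with known ground truth;
every stage is validated by parameter recovery against what was planted.

## Models

Minute *t* is scored sleep iff the weighted activity is below threshold:

    D_t = P * (W_-4 A_{t-4} + ... + W_0 A_t + ... + W_+2 A_{t+2}) < 1

with the published 1-minute-epoch weights (P = 1e-5; W = 404, 598, 326,
441, 1408, 508, 350), followed by Webster's five rescoring rules.  Within
each noon-to-noon day, the sleep interval [onset, offset) maximizes the
correlation between its indicator and the binary labels (the R^2-optimal
square wave); sleep hours, midpoint, and efficiency derive from it.

The proximal model for night-level sleep (minutes) of participant *i* on
0-based day *d*:

    sleep_id = b0*feedback_id + b1*(feedback_id x d) + beta' controls + u_i + e_id

with a participant random intercept u_i (REML); `b0` is the day-0 proximal
effect and `b1` its per-day decay.  Symptom models regress momentary EMA
scores on the six IIM/IIV features plus age and sex with a participant
random intercept; the slope on IIV of sleep hours is the reported
association.  The Bayesian cascade stacks the same sleep path with a
symptom path `symptom_{t+1} = kappa_i + theta*sleep_t + ...`; the mediated
effect on day *d* is the draw-wise product `(b0 + b1*d) * theta`, and a day
is "effective" when its 95% credible interval excludes 0 (Gibbs sampling,
4 chains, 8000 iterations, 4000 burn-in, convergence at Rhat < 1.10).

## Worked example

Simulate a two-study dataset and run every stage:

```sh
sleepjitai run --seed 3 --out demo_run
sleepjitai report --run-dir demo_run
```

prints:

```
run 0e72cbafab06a66f (seed 3)
proximal feedback effect: 34.2 min (95% CI 17.3 to 51.1), decay -3.2 min/day
cascade converged: True
groups: A=73 B=67
```

Reading: the cohort of 140 splits into 73 stable and 67 unstable sleepers;
on the first trial day a feedback message lengthens next-night sleep by an
estimated 34 minutes (the generator's group-B-only planted effect diluted
over the whole sample), and the effect decays by ~3 min/day.  The run
directory contains every intermediate table (nightly sleep records,
participant statistics, cluster assignments, decision log) and fit JSONs,
plus a provenance manifest.

The library surface mirrors the stages: `classify_cole_kripke`,
`apply_webster_rescoring`, `fit_sleep_square_wave`, `compute_iim_iiv`,
`ward_dichotomize`, `score_dams`, `decide_day`, `fit_proximal`,
`fit_symptom_models`, `fit_cascade`, `fit_distal_anova`, and the
`synthetic_cohort` generator.

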