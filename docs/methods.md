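# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the design decisions taken where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Sleep scoring

**Cole-Kripke classification.**  Each 1-minute epoch is scored from a
centred 7-epoch window of zero-crossing counts (4 minutes of history, the
current minute, 2 minutes of future), sleep iff
`1e-5 * (404 A_-4 + 598 A_-3 + 326 A_-2 + 441 A_-1 + 1408 A_0 + 508 A_+1 +
350 A_+2) < 1`.  The constants are the published coefficient set for counts
scored in 1-minute epochs and live in module-level config so alternates
can be swapped.  Boundary epochs use zero-padding.  Non-worn epochs are
forced to wake: off-wrist minutes usually record zero counts, which would
otherwise read as deep sleep.

**Webster rescoring** (applied on the raw classification, non-cascading):
after wake runs of >=4 / >=10 / >=15 minutes, the next 1 / 3 / 4
sleep-scored minutes are rescored wake; sleep runs of <=6 (<=10) minutes
flanked on both sides by >=10 (>=20) minutes of wake are rescored wake.
Rescoring only ever flips sleep to wake, so total sleep is monotonically
non-increasing — a property test asserts this on arbitrary inputs.

**Square-wave interval.**  Within each analysis day the single interval
[onset, offset) maximizes the Pearson correlation between its indicator
and the binary labels; the reported R^2 is the squared correlation.  We
maximize the *signed* correlation rather than R^2 itself because the
anti-correlated complement of a good interval attains the same R^2 and a
pure-R^2 criterion would be ambiguous between "the sleep block" and
"everything but the sleep block".  The search is exact: for each interval
length the best placement is the maximal sliding-window sleep count, and a
compiled scan covers all lengths.  A restriction to the span of
sleep-labelled epochs is used when provably equivalent (any optimal
interval no longer than half the window has sleep-labelled endpoints; an
explicit bound on the correlation attainable by longer intervals triggers
a full scan when needed).  Tie-break: among equal correlations, the
longest interval, then the earliest onset.  Sequences scored entirely
sleep return the whole window flagged degenerate; windows with no sleep
labels yield no record (the day is excluded, not zero-filled).

**Windowing and wear.**  Analysis days run noon to noon (standard
actigraphy convention; nocturnal episodes are never split).  A day is
skipped when fewer than 120 worn minutes overlap its window.  Sleep
efficiency is (sleep-labelled epochs inside the interval) / (interval
length); the alternative reading of the source description would exceed 1,
and the conventional ratio is consistent with low efficiency being
adverse.

## Intraindividual statistics

Participants with fewer than 4 scored nights are excluded.  Sleep hours
and efficiency use the ordinary mean and sample SD (n-1).  Midpoint of
sleep is circular (24 h = full circle): the IIM is the resultant-vector
direction and the IIV is `sqrt(-2 ln R) * 24/(2 pi)` hours.  Where the
midpoint enters linear models, distances, or standardization it is
re-expressed as hours since the preceding noon ([12, 36)), which is
continuous across midnight for nocturnal sleepers.  For clustering the six
features are z-scored across the cohort (population SD); for t tests and
ANOVA the IIV features are natural-log transformed (zeros floored at 1e-6
hours with a warning).  Standardization and log transform are deliberately
applied to different downstream consumers, mirroring the analysis split.

## Phenotyping

Agglomerative clustering with the Ward criterion on Euclidean distances
(scipy's `ward`, i.e. the ward.D2 convention — the variant used by the
original analysis is not recoverable, so the choice is documented and
isolated) cut at k=2.  Group labels are anchored deterministically: B is
the cluster with the larger mean standardized IIV of sleep hours, so
relabelling cannot depend on dendrogram orientation.  Group contrasts use
Welch t tests and Hedges g with the small-sample correction
`J = 1 - 3/(4 df - 1)`; no multiplicity correction is applied to these
descriptive comparisons.

## EMA scoring

Anxious / positive / negative moods are means of their adjective triplets;
the depressive score is implemented exactly as printed,
`(100 - (positive + negative))/2`, although its sign on negative mood is
counterintuitive; a `sign_corrected` variant is available behind a switch
and is never the default.  Records missing any adjective are skipped and
logged rather than imputed.

## MRT engine

One Bernoulli(0.5) draw per participant-day from a seeded stream
(randomize first, then gate), a data-sufficiency gate at >=720 uploaded
1-minute records for the preceding noon-to-noon day with a single 2 PM
retry and a BLE-check notice, relative sleep sufficiency in signed minutes
(last night minus the participant's observational-phase mean), and the
verbatim message templates.  A zero difference takes the "longer" wording.
Days randomized on but data-insufficient after the retry deliver no sleep
feedback and are analysed as no-feedback (a flag records them distinctly).

## Effect models

All frequentist fits are statsmodels `MixedLM` with a participant random
intercept, REML, Wald 95% CIs.  The proximal model controls for the prior
night's sleep hours, age, and sex (sex coded 0 = male reference);
zero-variance controls (e.g. a single-sex subgroup) are dropped with a log
note rather than crashing the fit.  The content-stratified variant
excludes other-stratum feedback nights instead of recoding them as 0, so
the reference level stays uncontaminated.  The symptom models use all six
IIM/IIV features plus age and sex as fixed effects (the original covariate
table is unavailable; this is the documented choice).  The distal 2x2
(study x group) ANOVA is fitted as `value ~ study*group + age + sex` with
a participant random intercept; F tests are squared Wald t statistics with
denominator df approximated by participants - 2, and the within-group
study contrasts are Tukey-adjusted over the four study-x-group cells via
the studentized range distribution.

## Bayesian cascade

The published model equations are not available, so the model is an
explicitly labelled reconstruction with the structure the reported
analysis requires: a sleep path
`sleep_it = alpha_i + (b0 + b1 d) feedback_it + gamma age + delta sex + eps`
with `alpha_i ~ N(mu, tau^2)`, and per-symptom paths
`symptom_{i,t+1} = kappa_i + theta sleep_it + ... + eps'`.  Feedback is
assumed to act on morning symptoms only through sleep (pure mediation), so
the cascading effect on day *d* is the product `(b0 + b1 d) * theta`,
computed draw-wise; a day is effective iff the 95% credible interval
excludes 0.  The day effect is linear-in-day by default (a per-day-dummy
basis would need far more data than 14 nights provide).

Every conditional is Gaussian or inverse-gamma, so the posterior is
sampled with a blocked conjugate Gibbs sampler written in-package:
N(0, 1000^2) priors on slopes and intercept means and inverse-gamma
(0.001, 0.001) on both variances (conjugate counterpart of a
weakly-informative half-normal; with ~900 observations the likelihood
dominates either choice).  Defaults are 4 chains, 8000 iterations, 4000
burn-in; convergence requires split-Rhat (arviz) < 1.10 for every tracked
parameter, and the counterfactual step refuses non-converged fits.  The
test suite runs the sampler at 1000/500, a problem size chosen so the
replicated calibration check (20 replicates) completes in well under a
minute while still exercising 4-chain Rhat.

## Synthetic cohort generator

The generator emulates the two-study structure with every planted quantity
recorded as ground truth and full bit-reproducibility from (config, seed).

*Phenotypes.*  Group A (stable): mean nightly sleep 7.3 h (between-person
SD 0.6), IIV of sleep hours log-normal with median 0.45 h; midpoint 03:00,
within-person midpoint SD median 0.45 h; within-sleep wake fragmentation
~2%/minute.  Group B (unstable): 6.5 h (SD 0.7), IIV median 1.4 h,
midpoint 04:00 with SD median 1.5 h, fragmentation ~7%.  Cohort 140
participants, 67 in group B, 14 nights, ages N(39.15, 10.09), 27.7%
female.  Per-participant nightly-SD draws are capped at 1.6 h and nightly
durations clipped to [2 h, 11.5 h]: beyond these the truncation itself
would distort the planted linear models (and SDs above 1.6 h are not
plausible sleep behaviour).

*Counts.*  Zero-inflated Poisson: sleep minutes are 0 with probability
0.75, else Poisson(3); wake minutes Poisson(150).  At these levels the
Cole-Kripke chain recovers planted intervals with ~7 minutes of systematic
edge erosion (the weighted window plus Webster rule a) and per-participant
measured IIV correlates > 0.98 with planted IIV.  Fragmentation levels
matter: much jitterier fragmentation makes the square-wave fit trim
fragmented nights erratically, inflating measured IIV and attenuating
every downstream slope — the defaults were chosen so the measurement chain
is faithful, which is what makes end-to-end recovery a meaningful test.

*EMA.*  Five prompts per day (wake, 15:00, 19:00, 11:00, bedtime).  A
participant's symptom level is `baseline + slope * IIV_SH,true + u_i`
with planted slopes +3.83 (depressive), +5.70 (anxiety), -3.37 (morning
sleep quality) per hour of true sleep-hour IIV, where the "true" IIV is
the realized SD of the planted nightly durations.  Baselines (15 / 30 /
60) sit mid-scale so VAS floor/ceiling clipping is negligible — placed
near a bound, clipping censors exactly the extreme-IIV participants and
biases the recovered slopes.  Adjectives are back-solved exactly from the
target scores (anxious triplet equal; positive/negative split 65/35 of
`100 - 2*depressive`), so the scoring formulas invert the generator by
construction.

*Trial.*  Nightly sleep responds to the day's feedback decision with
`resp_g * (b0 + b1 d)` minutes; defaults plant the reported heterogeneity
(group B responds with (59, -6), group A not at all), and a pooled-effect
variant plants (40, -4) in everyone for whole-sample recovery studies.
Next-morning symptoms follow the cascade path with theta = -0.05 (mood
units/minute) for depressive mood.  `iiv_scale_b < 1` emulates
intervention-driven stabilization for distal analyses.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: realistic accelerometer noise (naps, restless
wake, motion artefacts, device non-linearity), EMA non-response and
response styles, dropout and noncompliance beyond a simple missing-day
switch, weekday/weekend structure, and any direct (non-mediated) effect of
feedback on symptoms.  Recovery results certify the estimation machinery
under the stated model, not the validity of the model for any particular
device or cohort.

## Problem sizes

Replicated studies use 50 replicates for the mixed-model recovery checks
(n=67 trial cohorts; n=140 observational cohorts) and 20 replicates for
the scaled-down MCMC calibration; the randomization check uses 10,000
participant-days.  These sizes give Monte-Carlo standard errors on the
replicate means of roughly 2 minutes (proximal effects) and 0.2-0.4 units
(symptom slopes), small relative to the tolerances they are compared at.

## Known limitations

* The square-wave criterion assumes one main sleep episode per day; naps
  are absorbed or ignored, and split sleep will be summarised by whichever
  segment correlates best.
* The distal ANOVA's denominator df (participants - 2) and
  cell-based Tukey adjustment are approximations to the mixed-model
  ANOVA/lsmeans machinery of the original environment.
* The cascade model is a reconstruction; with per-day effect dummies the
  14-night design is weakly identified, so only the linear-in-day variant
  is exercised by default.
* Circular SD is reported in hours via sqrt(-2 ln R); for dispersions
  approaching the uniform distribution this quantity grows without bound
  and loses interpretability (antipodal configurations raise an error).
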