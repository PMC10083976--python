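# Methods

`traitchange` analyses four kinds of personality-trait change in a
multi-wave, multi-informant panel, plus the correlation of change across
traits and raters. This note documents the models, their assumptions, the
tunable parameters that matter, and the choices made where the design was
genuinely open.

## Data model and scoring

Observations live in a tidy long table (`LongPanel`): one row per person ×
rater × wave × variable, where a variable is either a raw Likert item
(1–5) or a scored scale. The emulated instrument is a Big Five Aspect
Scales design: 10 aspect scales of 10 items each (some reverse-scored),
every trait domain comprising the 20 items of its two aspects.

Scoring choices:

* **Scale score = mean of items**, not sum, keeping scores on the 1–5
  response metric. Monthly slopes of ~0.002 are then directly interpretable
  as Likert points per month.
* Reverse-scored items are transformed as `6 − x` (an involution).
* A person–wave scale score is the mean of available items when at least
  80% of the scale's items are observed, otherwise missing. The threshold
  is configurable (`min_item_coverage`); 80% is a common psychometric
  convention, and a domain score always averages its items (equivalently
  the item-count-weighted mean of its aspects when items are complete).
* Cronbach's alpha uses the standard variance-ratio form with n−1
  denominators, listwise over complete rows.

When several informants rated the same person, one informant with at least
two assessment waves is retained, drawn uniformly at random under an
explicit, logged seed; persons whose informants were all observed once keep
only self-reports and are tallied as ineligible.

## Synthetic panel generator

The generator (`synthetic.generate_panel`) emulates the design the analyses
assume so that every stage is testable with known ground truth:

* 259 persons at baseline with monotone attrition to 196/191/150 across
  four waves at months 0/6/13/19 (exact counts, not expectations);
* latent trajectories `level = (μ_k + u) + (β_k + v)·t + q_k·t²` with
  intercepts and slopes multivariate normal over traits (within-domain
  aspect correlation 0.5, cross-domain 0.15, intercept–slope correlation
  −0.2);
* informant reports whose latent levels correlate 0.5 and latent slopes 0.3
  with self-reports (both configurable — the study's informant-agreement
  magnitudes are not published, so these are free parameters);
* observed scale scores add occasion residual noise; items add parallel
  item noise whose variance is solved so that the scale's Cronbach's alpha
  equals its target in expectation (any target in (0, 1] is attainable);
* optional rounding/clipping to the 1–5 Likert grid. Rounding is on by
  default for realism and off in oracle tests, because it breaks exact
  closed-form checks (and attenuates realized alpha by a few hundredths).

Default variance components (intercept SD 0.45, slope SD 0.015/month,
residual SD 0.15) are the package's own choices: no variance-component
estimates are published for the emulated study, so they were fixed once, by
power analysis, at values that make individual slope differences detectable
at n = 259 while keeping cross-wave stability in the realistic 0.7–0.85
band. Passing tests therefore demonstrate correctness of the machinery
under a plausible data-generating process, not fidelity to the archived
sample. Real data differ in ways the generator does not emulate: skewed and
censored item distributions, non-normal person effects, informant-specific
response styles, and non-random attrition.

A two-wave cohort builder (`make_profile_change_cohort`) plants known
profile-change types — none, elevation only, elevation+scatter,
elevation+scatter+shape — for classification tests. Elevation adds a
constant (default 1.0 score points), scatter multiplies deviations from the
person-profile mean (default factor 4), shape sign-flips (or permutes)
those deviations. The defaults were fixed in advance from a closed-form
sensitivity analysis: a scatter change must move the deviation-score
distance past a null cutoff of roughly `2(1−α)σ²·χ²₍ₖ₋₁₎` even for persons
whose own trait deviations are modest, which a factor-4 rescaling does once
trait means are spread across the profile (as Big Five norms are). With
near-identical trait means the standardized-distance null degenerates
toward its algebraic maximum `4(k−1)` and shape change becomes undetectable
— a structural feature of ipsative indices worth knowing before applying
them.

## Mean-level change (growth models)

Per trait and rater role, `value ~ 1 + month` is fitted by linear
mixed-effects regression (statsmodels `MixedLM`) with person-level random
intercepts and random month slopes (unstructured 2×2 covariance). The
quadratic model adds a fixed `month²` term only, keeping the random
structure — the curvature question is about the average trajectory, and a
single added fixed parameter gives the df = 1 likelihood-ratio comparison.

Numerical choices:

* Internally, time is rescaled to the observation span (months/19 under the
  default design) so the random-slope variance is on the same order as the
  intercept variance; estimates are mapped back to per-month units. This
  removes essentially all boundary non-convergence. If a fit still fails to
  converge, one retry at a 10× coarser time scale is attempted, then the
  fit is returned flagged — never silently replaced.
* All likelihood-ratio tests use ML log-likelihoods (REML comparisons are
  invalid across nested fixed effects; one consistent rule is simpler to
  verify). REML log-likelihoods are retained alongside when requested.
* Fixed-effect p-values use t statistics with approximate df =
  n_persons − (number of fixed effects); the df method travels in the fit
  metadata. Satterthwaite df would differ slightly but `MixedLM` does not
  expose them.
* The pipeline-wide significance threshold is 0.01.

Individual differences in change are tested by comparing the
random-intercept-only and random-intercept-plus-slope linear models
(df = 2: slope variance + covariance). The naive χ²₂ reference is
conservative because the slope variance sits on the boundary of its
parameter space under the null; the 50:50 χ²₁/χ²₂ mixture p-value is
reported alongside.

Per-person slopes are the fixed month coefficient plus each person's
predicted random deviation (BLUP). BLUPs are shrunken, error-contaminated
estimates: their correlation with true slopes is bounded by the square root
of the slope-estimate reliability, ≈ `√(σ²_slope / (σ²_slope + σ²_occ/Sxx))`
with `Sxx = Σ(t−t̄)² = 205` under the 0/6/13/19 design. With realistic
occasion noise this bound sits far below 1; recovery tests that demand high
BLUP–truth correlation therefore use low-noise fixtures, and downstream
slope correlations are reported without disattenuation (a known caveat, as
in the literature this mirrors).

## Rank-order stability

Cross-wave Pearson correlations are computed per trait on pairwise-complete
persons (no imputation), with per-cell n always reported and cells under 4
pairs marked unavailable. The stability-increase test compares r(1,2) with
r(3,4) on the Fisher z scale. Two variants are reported:

* **independent** (default): `z = (z_late − z_early)/√(1/(n_e−3) + 1/(n_l−3))`
  — the textbook two-sample form, which ignores that the wave pairs share
  persons and is conservative under positive dependence;
* **dependent**: a Steiger-type statistic using the Pearson–Filon
  covariance from the 4-wave correlation matrix on persons complete at all
  four waves.

One- and two-sided normal p-values are both attached; reported z/p
conventions in the literature for this test are not always internally
consistent, so the package labels its own convention explicitly rather than
matching any particular printed pairing. The temporal-decay table carries a
step-ladder diagnostic: whether adjacent-wave correlations increase,
r(3,4) > r(2,3) > r(1,2).

## Ipsative profile change

A person's profile at a wave is the ordered vector of k scale scores (5
domains or 10 aspects). Squared Euclidean distances between two waves are
computed on raw (D²), mean-deviated (D′²), and standardized (D″²) profiles
— the Cronbach–Gleser decomposition into elevation, scatter, and shape.
With the k−1 SD convention the identities

    D² = D′² + k·(Δ elevation)²          D″² = 2(k−1)(1 − r_profile)

hold exactly and are enforced as tests; D″² is bounded by 4(k−1). Flat
profiles (SD = 0) have no standardized form; such person-waves are excluded
from D″² and counted in a reported tally rather than zeroed. The default
wave pair is (first, last); all pairs are computable behind a flag, and
summaries are emitted per wave pair without claiming either aggregation
matches any particular published percentage.

### No-change null

Whether an observed distance is "real" change is judged against a simulated
null in which the true profile never changes and only measurement error
moves the observed scores. For each of 50,000 simulated participants a
single true profile is drawn from a multivariate normal whose covariance is
the observed covariance with variances attenuated to `α_k·σ_k²`
(off-diagonal covariances retained, repaired to nearest-PSD with a logged
warning if attenuation breaks positive semidefiniteness); each wave
observes that profile plus independent error of variance `(1−α_k)·σ_k²`.
This is the minimal model satisfying the three published constraints such
simulations cite: observed moments reproduced, perfect true-score
stability, and per-trait retest correlation equal to the scale's alpha.
Whether real analyses also attenuate the covariances is not documented
anywhere we know of; retaining them is this package's choice, isolated
behind the calibration object. Calibration moments default to wave-1
observed statistics.

The middle `interval_mass` (default 99.9%) of each simulated index gives
the cutoffs; a distance exactly on a cutoff is *not* change (strict
exceedance). In the univariate case the null D² is exactly
`2(1−α)σ²·χ²₁`, used as a closed-form cross-check. Cutoffs serialize to
JSON with calibration, seed, and n_sim so classification is reproducible.

## Correlated change

Extracted slopes are correlated across trait pairs within rater and, per
trait, between self- and other-reports, untransformed (Pearson r is
scale-invariant), with per-cell n and cells under 4 pairs unavailable.
Baseline (wave-1) self–other level agreement is computed alongside, since
level agreement and change agreement routinely diverge. Informant-type
moderation fits `self_slope ~ other_slope × type` by OLS per trait
(family vs friend/roommate); with one type present (or a group under 5
persons) a flagged main-effects model is returned instead.

## Pipeline

`run_pipeline` chains the stages (simulate/ingest → informant selection →
scoring → growth → rank-order → profile change → correlated change),
writing CSV/JSON tables plus a manifest with seeds, a config hash, and
per-stage exclusion counts (persons without eligible informants, flat
profiles, small-n cells). All randomness flows from three named seeds —
generator, informant selection, null simulation — so each stochastic stage
is independently reproducible; identical configs produce byte-identical
numeric outputs. When the input panel carries no informant metadata,
informant types for the moderation stage are assigned at random under the
informant-selection seed and recorded.

## Verification problem sizes

The test suite verifies statistical calibration at sizes chosen by the
package: null-interval coverage with 50,000-draw cutoff and cohort
simulations; classification sensitivity on labelled cohorts of 2,900
persons; 2-SE coverage of the fixed slope over 200 replicate REML fits at
150 persons each; type-I error of the four inferential tests over 500
replicates (mixed-model tests, at 80–100 persons per replicate) or 1,000
replicates (z-difference and moderation tests), judged against 99% binomial
bands around the nominal 1%; and a Kolmogorov–Smirnov check of the
univariate χ² null at 10,000 draws. The 2-SE coverage check is
intrinsically sharp: nominal coverage of a ±2·SE interval is 95.45%, so a
≥95% pass mark over 200 replicates leaves less than half a standard error
of margin even for a perfectly calibrated estimator.

## Known limitations

* No multiple imputation and no pooling across imputed datasets; mixed
  models handle attrition under a missing-at-random assumption, and
  correlations surface their pairwise n instead.
* No latent-variable (SEM) growth or stability models.
* Approximate fixed-effect df (no Satterthwaite/Kenward–Roger).
* Slope correlations are attenuated by BLUP estimation error and are not
  disattenuated.
* The study span is treated as 19 months (the wave-4 time code);
  descriptions of comparable designs sometimes round the same design to
  1.5 or 2.5 years, and any such label is avoided in outputs.
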