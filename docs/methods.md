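# Methods

This note records the measurement model, the numerical choices, and the
design decisions behind `vocabcat`, together with what the synthetic-data
generator does and does not emulate.

## Measurement model

All scored responses are dichotomous and follow the Rasch (one-parameter
logistic) model, `P(x=1 | θ, b) = expit(θ − b)`, with person ability θ and
item difficulty b on a shared logit scale. The model deliberately has no
discrimination or guessing parameters: item quality is handled by misfit
screening rather than extra parameters, and guessing pressure is managed
by the instrument design (multiple-choice distractors, pseudoword
controls) rather than a lower asymptote.

Three stimulus kinds are administered under fixed quotas (default
60/20/20 of a 30-item session):

* **binary** — self-report yes/no; "know" scores 1.
* **multiple-choice** — claiming "know" triggers a four-option definition
  question (one synonym, three distractors, order randomized per
  presentation). Choosing the synonym scores 1; a wrong choice scores 0
  by default (`mc_wrong_scores_zero=False` leaves it unscored for
  ability, affecting only the attention index — the two readings of the
  protocol differ and the flag preserves both).
* **pseudoword** — never scored; claiming to know one is recorded as a
  warning and feeds the attention index.

## Item calibration

`calibrate_items` fits difficulties by marginal maximum likelihood via
EM with a Normal(0, σ²) ability prior. The prior mean is fixed at 0 for
identification; σ is estimated in the M-step. Abilities are EAP
posterior means under the fitted prior. Convergence is max |Δb| < 1e−6
or 500 EM cycles, with a safeguarded Newton inner loop per item.

**Quadrature.** The posterior is carried on 91 equally spaced nodes on
[−12, 12] logits (spacing ≈ 0.27). The range must extend several logits
past both the bank's difficulty span and the bulk of the ability
distribution: with abilities spread over roughly ±3 SD ≈ ±9.4 logits
around the mean, truncating extreme respondents' posteriors at a tighter
boundary (e.g. ±8) shrinks their contribution, underestimates σ, and
visibly compresses the recovered difficulty scale at the extremes. The
wider grid removes that artifact at negligible cost.

**Degenerate items.** Items whose observed responses are all-correct or
all-incorrect have no finite maximum-likelihood difficulty; they are
reported as `non_estimable`, never silently dropped or imputed.

**Scale identification and recovery metrics.** Because the origin of the
logit scale is fixed by the prior mean (not by the generating truth),
recovered and true difficulties are comparable only up to a translation.
Recovery studies therefore report both the raw RMSE and the RMSE after
removing the mean error (mean-mean linking). Rescaling is *not* removed:
the Rasch model has a fixed unit, so a multiplicative misfit would be a
genuine error, not an identification freedom.

## Fit statistics and reliability

With P the model probability, W = P(1−P), and standardized residual
z = (x − P)/√W, the unweighted (outfit) and information-weighted (infit)
mean squares per item or person are

    outfit = mean(z²)        infit = Σ W z² / Σ W

over that entity's scored cells; both have expectation 1 under the
model. Standardized forms use the Wilson–Hilferty cube-root transform
`z = (MSE^{1/3} − 1)(3/q) + q/3`, with q² the model variance of the mean
square computed from the Bernoulli residual kurtosis
C = E[(x−P)⁴] = P(1−P)[(1−P)³ + P³]:

    q²_outfit = (Σ C/W² )/N² − 1/N
    q²_infit  = Σ (C − W²) / (Σ W)²

Missing cells (never administered) contribute to no sums — adaptive
missingness is structural, not informative about fit.

Reliability of separation for a set of estimates with standard errors:
observed variance SD²_obs, mean error variance MSE = mean(se²), adjusted
variance max(SD²_obs − MSE, 0), reliability R = adjusted/SD²_obs,
separation G = √(adjusted/MSE), STRATA = (4G+1)/3. R = G²/(1+G²) by
construction. Misfit screening on recalibration flags an item only when
a mean square exceeds 1.3 **and** a standardized fit exceeds 2.0 in
absolute value (strict inequalities); an `"or"` rule is available since
the conjunction is a documented reading choice.

## Adaptive administration

* **Kind schedule**: per-kind targets by the largest-remainder method,
  spread over the session by largest-remainder spacing, then shuffled by
  the session RNG under the constraint that no two pseudowords are
  adjacent. The proportions are a design quantity; the ordering is not,
  and spacing avoids clustering the control items.
* **Item selection**: among unadministered active items of the scheduled
  kind, the `randomesque_k = 3` items nearest in difficulty to the
  current ability estimate, one picked uniformly (exposure control).
  Pseudowords have no difficulty and are drawn uniformly without
  replacement. If the scheduled kind has no eligible item, the next kind
  with remaining quota is used.
* **Interim and final estimator**: EAP under a Normal(0, 3²) prior — the
  standard CAT choice because it stays finite for all-correct and
  all-incorrect patterns; ML estimation (with its divergence on extreme
  patterns signalled explicitly) is available for analysis.
* **First item**: selected at θ = 0; a bank-median start is a config
  alternative (`initial_theta`).
* **Stopping**: fixed length (30 by default). No SE-threshold stopping.

## Scoring

`logits_to_words` clamps the logistic conversion to [0, a] before
rounding to an integer word count (user-facing value). The conversion
coefficients (b, c) are fit to (frequency rank, difficulty) pairs of the
active calibrated items by derivative-based nonlinear least squares with
a 3×3 multistart over b ∈ {0.1, 0.5, 1.0}, c ∈ {−2, 0, 2} (logistic fits
are prone to bad local optima); a is fixed, not estimated.

**Attention index** = 100·(x+y)/(ax+ay): x of ax presented pseudowords
rejected, plus y of ay *reached definition questions* answered with the
synonym. The denominator counts definition stages reached (i.e.
multiple-choice items where "I know" was claimed), not all
multiple-choice presentations: under adaptive difficulty matching a
respondent knows roughly half of the presented words by construction, so
counting unreached definitions would make the index an ability measure
(≈72% for perfectly attentive respondents) instead of an attention
measure. As defined here the index is ability-independent — definition
correctness *given* a claim, plus pseudoword rejection — which is what
lets a single threshold separate careless from attentive respondents at
every proficiency level. The trust threshold defaults to 70% and is a
parameter (75% is a plausible alternative reading of the cleaning
procedure).

## Session filtering and recalibration

Rules apply in a fixed order: honesty confirmation, attention < 70,
duration < 60 s, age < 7 years — each checked on every session so an
exclusion lists all triggered reasons — then a single pass of the
mean ± 2 SD rule on vocabulary size within each nativeness group,
computed over the sessions surviving the earlier rules (so attention and
duration artifacts cannot pollute the group statistics). All thresholds
are strict. A group with fewer than 3 survivors skips the outlier rule
with a warning. The outlier pass is not iterated: one pass mirrors a
single cleaning step, and iteration would not be idempotent in general.

Suspected repeat attempts — sessions within 5 minutes of each other with
identical reported (age, nativeness), chained transitively — are flagged
for inspection but never removed.

Recalibration: filter → assemble the person×item matrix (pseudoword and
unscored entries stay missing) → MML calibration → fit screening →
write-back of difficulties/SEs into active items (pseudowords never
acquire difficulties) → conversion refit on the surviving active items.

## Validation statistics

* Pooled (equal-variance) independent-samples t from group summaries;
  the pooled form is identified by the convention df = n₁+n₂−2. Sign
  convention: group 2 minus group 1.
* Cohen's d = (m₂−m₁)/s_p with 95% CI from the large-sample variance
  (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)) and normal quantiles.
* Pearson r with Fisher z = atanh(r); |r| at the floating-point boundary
  of 1 yields ±∞, flagged rather than hidden.
* Skewness: adjusted Fisher–Pearson (the common statistics-package
  default); undefined below n = 3 or at zero spread.
* Age curves: 11 equal-width bins over the observed age range by
  default; equal-count binning is a config option.

## The synthetic-data generator

The simulator emulates the statistical structure the method assumes:

* **Abilities**: normal on the logit scale. The generic default (mean
  0.18, SD 3.12 logits) matches the pooled person distribution of a
  large validation sample of natives and learners. The native preset
  uses a linear age–ability link (slope 0.1 logits/year over ages 12–66,
  residual SD 2.70, keeping the marginal SD near 3.12) chosen so the
  age–ability correlation is ≈ 0.5, the magnitude reported for native
  speakers; the learner preset (mean −3.6, SD 1.3, ages 8–49, no age
  link) places its vocabulary-size distribution an order of magnitude
  below the native one, as observed.
* **Banks**: real-word difficulties evenly spread with jitter over
  [−7, 6] logits (the span a realistic vocabulary bank covers), ranks
  assigned by the inverse logistic rank rule with true coefficients
  (a = 140,000, b = 0.8, c = 0), so easier ⇒ smaller rank, strictly.
  The default c ≈ 0 places the native mean near 75,000 words.
* **Careless responding** is a response-level mixture: with probability
  `careless_response_rate` (default 0.75) a careless respondent answers
  each item at random (know/don't-know at ½, a uniform option if a
  definition stage is reached). Modelling carelessness per item rather
  than as a degraded ability matches what the attention index can
  detect. Attentive respondents claim pseudowords known at a 5%
  false-alarm rate; multiple-choice lucky guessing defaults to 0 (a
  guessing option exists to probe robustness).
* **Durations**: lognormal with median 113 s (σ = 0.3), echoing observed
  mean test durations; used only to exercise the duration filter.

What it does **not** emulate: real lexical material (item texts are
placeholders), education/print-exposure covariates, differential item
functioning, response times per item, learning or fatigue within a
session, and non-normal ability distributions — in particular, a pooled
native+learner cohort is bimodal, which violates the normal-prior
assumption of MML calibration and visibly distorts recovered
difficulties; recovery studies therefore default to the single pooled
normal population, and robustness to mixtures can be probed by passing
both presets explicitly. Passing tests on simulated data consequently
demonstrate the correctness and statistical calibration of the
machinery under the model's own assumptions, not the behaviour of any
real item bank or population.

## Problem sizes used in the test suite

The end-to-end recovery study runs 2,000 sessions against a 300-item
bank (the acceptance-scale study); the error-monotonicity check runs
250/500/1,000 sessions against a 150-item bank; null-distribution fit
checks use 5,000×100 fully crossed responses; unit studies use
100-item banks. These sizes are chosen so each check is comfortably
beyond its small-sample regime while the whole suite stays fast.

## Known limitations

* The mean ± 2 SD outlier rule is not idempotent for arbitrary
  distributions (removing outliers shrinks the SD); it is applied once,
  by design.
* MML assumes the latent distribution is normal; see above.
* Difficulty recovery at bank edges is limited by how many respondents
  the ability distribution places there; reported SEs reflect this.
* The CAT engine assumes a calibrated bank; cold-starting an uncalibrated
  bank (difficulty-free real words) is out of scope.
* STRATA is reported from the standard formula (4G+1)/3 per axis; values
  computed under other conventions are not targeted.
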