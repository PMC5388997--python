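# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the known limitations of `gaitlda`.

## Canonical discriminant model

Observations are rows x ∈ ℝᵖ of gait parameters with group labels
(g groups).  Writing S_W for the pooled within-group scatter and S_B for
the between-group scatter about the observation-weighted grand mean, the
canonical axes solve S_B v = λ S_W v.  The model assumes each group is
Gaussian with its own mean and a *common* covariance matrix; membership
probabilities are the corresponding posterior
P(k|x) ∝ πₖ exp(xᵀΣ⁻¹μₖ − ½ μₖᵀΣ⁻¹μₖ), with Σ the pooled covariance
(divisor n − g).  At most r = min(g − 1, p) axes carry signal; the
canonical correlation of axis i is √(λᵢ/(1+λᵢ)) and the variance
explained λᵢ/Σλ.

Numerical choices:

* **Eigen-route.** S_W is Cholesky-factored (S_W = LLᵀ) and the symmetric
  matrix L⁻¹S_B L⁻ᵀ eigendecomposed; this avoids the non-symmetric
  S_W⁻¹S_B and keeps eigenvalues real and non-negative (clipped at 0
  against rounding).  Rank deficiency is detected on the eigenvalues of
  S_W *before* factorizing, because Cholesky can survive an exactly
  collinear scatter on a rounding-noise pivot; the error names the
  variables spanning the null space.
* **Scaling and sign.** Axes are scaled to unit pooled within-group score
  variance (standard canonical-variate scaling) and flipped so each
  axis's largest-magnitude coefficient is positive.  Both conventions are
  arbitrary but fixed, so results are reproducible across linear-algebra
  backends.
* **Priors.** Default proportional to group sizes — in this longitudinal
  design group sizes encode real sampling density across ages; equal
  priors are available by flag.
* **Posteriors.** Computed from linear discriminant scores through a
  softmax (log-sum-exp stable); they sum to 1 to ≤1e−12 even for queries
  tens of standard deviations from the data.
* **Ties.** `classify` breaks exact posterior ties to the first group in
  the model's (sorted) group order.
* **Singular designs and the ridge.** The three power fractions sum to
  exactly 1, so whenever all of CCP/TP, DVP/TP, MLP/TP are explanatory
  the within-group scatter has an exact null direction.  The core fitter
  treats this as a hard error unless a ridge is requested
  (λ·trace(S_W)/p added to the diagonal).  The gait-model layer enables a
  tiny ridge (1e−8) automatically when the exact fit is singular: because
  the observations *and* every group mean lie in the same
  fraction-closure hyperplane, the ridge direction carries zero
  between-group signal and zero within-group variation, so projections,
  posteriors and classifications are unaffected to within floating-point
  noise.  The same ridge is reused by every leave-one-out refit and
  stored with the serialized model.
* **Leave-one-out.** The shipped implementation refits on each n−1 subset
  exactly (no downdating shortcuts); the test suite verifies bit-exact
  agreement with an independent refit loop.  A p=8, ~1100-row, 37-class
  validation completes in a couple of seconds.
* **Ellipses.** `confidence_ellipse` fits a bivariate normal to 2-D
  scores and scales the covariance eigendecomposition by the χ²₂ quantile
  of the level.  The default is the observation-coverage ellipse (drawn
  around training classes, which visibly contain their point clouds);
  `of_mean=True` divides the covariance by n, giving the standard-error
  ellipse used for centroid trajectories.  Degenerate (rank < 2)
  covariances are an error, not a silent fallback.

## The three model designs

* Model 1: dependent variable = genotype; explanatory = the seven gait
  parameters.  Two groups, hence exactly one canonical axis.
* Model 2: dependent classes = genotype × half-month age class;
  explanatory unchanged.
* Model 3: Model 2's classes with age in days appended as an eighth
  explanatory variable.

Ages are converted with a 30.4375-day month (365.25/12) and binned by
floor into half-month classes (a 2.49-month dog is in class 2.0, matching
the left-edge naming GRMD_2, GRMD_2.5, …).  Classes with fewer than 3
observations (configurable) are dropped with a warning and the *realized*
class count is reported — sparse edges of the schedule need not populate
every nominal class.  Cohorts other than Healthy/GRMD (e.g. treated dogs)
are excluded from training and only evaluated against the fitted model.

Which canonical axis separates genotypes is detected empirically: the
axis maximizing the between-phenotype centroid gap divided by the
within-phenotype spread of class centroids.  The standardization matters:
in an age-augmented fit the dystrophic dogs' longer follow-up (to 12
months vs 9.5) shifts the raw mean of the *age* axis between phenotypes,
so an unstandardized gap would select the wrong axis.  On default
synthetic cohorts the detected axis is F1 for Model 2 and F2 for Model 3,
with all dystrophic class centroids on one side and all healthy centroids
on the other.

## Phenotype calling

For each dog session (one or two replicate 10-s sequences at one age),
the healthy membership is the posterior mass summed over all
Healthy-labelled classes, averaged across the session's replicates.  A
session with p > 0.95 is healthy-like, p < 0.05 GRMD-like, otherwise
intermediate — boundary values are intermediate because the inequalities
are strict.  A dog is called Healthy (GRMD) only when strictly more than
half of its sessions are healthy-like (GRMD-like); exact halves and
fragmented patterns are inconclusive ("n.c.").  Averaging within a
session rather than summing across time points is the only reading
consistent with probability-scale thresholds: a sum over many sessions
would exceed 1.

## Treatment evaluation

A treated cohort is projected onto the model's (F1, F2) plane; per
half-month age class the display shows the centroid, the 95 %
standard-error ellipse of the mean, and a colour: green if the class's
mean healthy membership exceeds 0.95, red below 0.05, yellow between.
Colours depend only on membership probabilities, never on the cohort
label.  For readability the age-in-days axis is projected onto the plane
by least-squares regression of age on the training (F1, F2) scores; the
in-plane gradient gives the axis direction and a days-per-unit-score
scale, with ticks at whole months.  The regression choice is a design
decision (any monotone calibration of the plane against age would do) and
is exposed as a returned direction/scale pair rather than baked into the
plot only.

## Synthetic cohorts

The generator emulates the study conditions directly at the level of the
seven derived gait parameters (raw 3-axis acceleration signals and their
vendor-side processing are out of scope):

* **Design.** 8 healthy and 20 dystrophic dogs (plus an optional treated
  cohort, default 6), sampled every 15 days from 2 months to 9.5 months
  (healthy, treated) or 12 months (dystrophic); each session yields two
  sequences, the second dropping out with probability 0.05 (healthy),
  0.35 (GRMD) or 0.25 (treated) — dystrophic dogs often cannot complete
  the second run.  A per-dog uniform ±7-day birth-date offset
  desynchronizes age in days within a session.  Nominal sessions start at
  68 days so the realized half-month classes span exactly 2.0–9.5 and
  2.0–12.0 months.
* **Generative model.** Observation = cohort mean trajectory at the dog's
  age + per-dog random intercept + multivariate Gaussian noise with a
  single 7×7 covariance shared by all cohorts and ages — precisely the
  homoscedasticity the discriminant model assumes, making the generator a
  faithful null for it.  Mean trajectories are linear in age (an optional
  saturation age flattens them); power fractions are clipped to (0, 1)
  and renormalized to sum to exactly 1; SF, TP and SL/HW are floored at a
  small positive value.  Regularity is emitted as an unbounded Gaussian
  and the strict Reg > 70 filter applied afterwards, mirroring the
  post-hoc exclusion used on real recordings.
* **Defaults.**  No per-variable means or SDs were ever published for
  either genotype, so the defaults are the package's own calibration,
  chosen once to reproduce the qualitative structure: at every sampled
  age the dystrophic means are lower for TP, Reg, SF and SL/HW and the
  power is shifted cranio-caudal → medio-lateral (healthy TP 18 + 2.2/mo
  vs GRMD 11 + 0.3/mo W/kg; SL/HW 1.15 + 0.02/mo vs 0.95 − 0.01/mo;
  MLP/TP 0.21 − 0.002/mo vs 0.30 + 0.003/mo, etc.).  Noise SDs (e.g. 3.0
  W/kg for TP, 0.10 for SL/HW) make the genotype gap large (≈6 pooled
  SDs in Mahalanobis distance) while age slopes over half a month stay
  well inside the noise, so adjacent age classes overlap heavily — this
  is what produces the characteristic pattern of high full-class but
  near-zero genotype-level misclassification.  Modest cross-correlations
  (TP–SL/HW 0.4, CCP–MLP −0.5, …) keep the covariance realistic and
  positive definite.  Per-dog random-intercept SDs are ≈⅓ of the noise
  SDs, modelling inter-individual variability.
* **Treatment.** Treated means are GRMD + f(age)·(Healthy − GRMD); the
  default fraction f decays linearly from 0.9 at 2 months to 0 at 7
  months (clipped to [0, 1]) — a partial, temporary benefit that makes
  the colour code run green/yellow → red with age.  A constant-fraction
  override supports the limiting cases (1.0 ⇒ indistinguishable from
  healthy, 0.0 ⇒ pure dystrophic).
* **Determinism.** One `numpy` generator seeded from the config drives
  every draw; identical configs give byte-identical tables.
* **What it does not emulate.**  Real dogs have heteroscedastic,
  age-dependent noise, non-Gaussian tails, gait-speed confounding, missed
  sessions and early loss of ambulation; none of these are simulated
  (right-truncation of individual dogs is available but off by default).
  Passing tests therefore demonstrate the correctness and internal
  consistency of the pipeline under its own assumptions, not that the
  defaults match any real colony's distributions — the published
  misclassification rates came from a cohort that is not publicly
  deposited and are not reproduced here.

## Problem sizes

The default cohort yields ≈1100 regularity-filtered observations in 37
classes; leave-one-out validation of all three models, the 20-dog blind
test and the treatment evaluation together run in a few seconds, and the
whole test suite in well under a minute.

## Known limitations

* The ridge fallback, while numerically inert for fraction-closure
  collinearity, is not a general-purpose remedy: genuinely collinear
  *informative* variables should be removed instead.
* Phenotype calling assumes the class table partitions into exactly two
  phenotypes; multi-arm designs would need an extended rule.
* The age-axis projection is linear; if age mapped curvilinearly onto the
  plane the whole-month ticks would be unevenly spaced (they are not, on
  the synthetic cohorts).
* Quadratic discriminant analysis, stepwise variable selection and
  probability recalibration are deliberately out of scope.
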