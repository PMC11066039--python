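# Methods

`pdprog` implements a complete pipeline for data-driven subtyping of
Parkinson's disease (PD) progression from longitudinal clinical scores, and
for translating the resulting subtypes into prognostic-enrichment trial
designs.  Because the clinical cohorts such analyses are run on are
access-restricted, the package ships a synthetic-cohort generator with the
statistical structure the analysis assumes; every stage is exercised end to
end on these cohorts.

## Latent-time joint mixed-effects model (LTJMM)

K outcomes progress jointly and linearly on a *common disease timescale*:

    y_ijk = x_i' beta_k + gamma_k (t_ijk + delta_i) + a0_ik + a1_ik t_ijk + e_ijk

for outcome k, visit j, patient i, with time t measured in years since
clinical diagnosis.  All outcomes are min-max normalized on their theoretical
range and direction-aligned (higher = worse) before fitting, so the mean
slopes gamma_k are in normalized units per year.  The latent shift
delta_i ~ N(0, sigma_delta^2) is shared across outcomes and aligns each
patient with a population "mean patient": a patient diagnosed unusually early
gets a negative shift.  Random intercepts and slopes (a0_ik, a1_ik) are
bivariate normal per outcome, independent across outcomes by default (a
parsimony choice keeping the parameter count linear in K); residuals are
Gaussian with per-outcome variance.  Covariates x_i are an intercept,
centred age at diagnosis, and sex (0/1, mapping recorded in metadata), acting
additively on the intercept level.

Assumptions worth stating: progression is linear *within the observation
window* (not across the whole disease course); bounded scales are treated as
continuous inside the model; delta is identified only through its shared
effect gamma_k * delta_i across outcomes (with a single outcome it is
confounded with the random intercept, and the fit warns).  The model is
invariant to a global time translation, so delta estimates are centred to
mean zero after every update with the shift absorbed into intercepts.

### Inference

The default backend is expectation-maximization on the marginal posterior
("MAP").  The E-step is exact: per patient, the joint posterior of
(delta_i, a0_i., a1_i.) is Gaussian and computed in closed form, including
all cross-covariances.  The M-step updates fixed effects (with
posterior-variance corrections), residual variances, random-effect
covariances and sigma_delta in closed form under weakly-informative priors
(normal(0, 5) on fixed effects, inverse-gamma(1.5, 1e-5) on residual
variances, inverse-gamma(1.5, 0.5) on sigma_delta^2, inverse-Wishart on the
2x2 random-effect covariances).  The reported objective is the exact marginal
log-posterior; it is non-decreasing over iterations (this is asserted in the
tests) and convergence is declared at a relative improvement below 1e-8.

The optional MCMC backend is a Gibbs sampler: every full conditional is
conjugate (Gaussian for fixed effects and the per-patient latent block,
inverse-gamma / inverse-Wishart for variances), chains are seeded
independently from one master seed, and convergence is gated at R-hat < 1.05
(arviz).  On our fixtures the Gibbs point estimates match MAP closely, but
the residual-variance / random-slope coupling mixes slowly with ~5 visits per
patient, so short desk-scale chains are honestly flagged as unconverged; the
defaults (4 chains x 2000 iterations, half warm-up) are a compromise, and
everything downstream uses point estimates, which is why MAP is the default.

### Held-out validation

`heldout_last_visit_r2` refits the model with every patient's last visit
removed (patients with fewer than 3 visits keep all data and are counted as
skipped) and reports pooled R^2 of the predictions for the excluded
measurements on the normalized scale, with the total sum of squares taken
about the per-outcome *training* mean — so predicting the training mean gives
exactly R^2 = 0.  On a fixture calibrated so that the generating model itself
achieves a moderate R^2 (~0.5-0.6, the regime reported for real PD cohorts),
the pipeline tracks the generating-model oracle within 0.1.

## Progression scores

From a converged fit, predicted trajectories are evaluated on a regular grid
of the common timescale (default 0-8 years in 1-year steps; yearly steps
match annual visit schedules and keep the sequences short) and standardized:

    score_ik(t) = (yhat_ik(t) - yhat_ik(0)) / sd0_k ,

where sd0_k is the sample SD (n-1) across patients of the predicted value at
the origin.  Scores are exactly 0 at the origin and exactly linear in t under
this model.  Because the scores are functions of the *fitted model*, they are
evaluated on the full grid by default.  An alternative mode masks grid points
outside each patient's observed common-timescale window; we implemented both
and found that with realistic time-shift SDs the masking removes almost half
the grid and the clustering then latches onto the missingness pattern rather
than progression speed, so full-grid evaluation is the default and the
masking mode is kept for sensitivity analysis.

## Subtype discovery (VaDER-style clustering)

Trajectory tensors (patients x grid x outcomes) are clustered with a
recurrent variational autoencoder whose latent prior is a k-component
diagonal Gaussian mixture, so cluster responsibilities come directly from the
latent space.  Missing entries pass through a trainable imputation layer
before encoding and are excluded from the reconstruction loss.  The
implementation is pure numpy with hand-derived backpropagation-through-time
(verified against numerical differentiation in the tests); encoder and
decoder are single-layer tanh recurrences with hidden size = latent size =
`hidden_nodes` — with sequences of at most 9 steps, gated units add
parameters without benefit.  Training follows the usual variational
deep-embedding recipe: reconstruction-only pretraining (50 epochs),
mixture initialization by a Gaussian mixture on the pretrained latent means,
then 50 joint epochs with a KL warm-up over the first half and damped
closed-form mixture updates (both guard against the classic early collapse
of the mixture onto one component); responsibilities are treated as constants
within each gradient step; after training the mixture is re-estimated to
convergence at the trained encoder.  Default learning rate 0.01, batch 32,
hidden 8, all drawn from the hyperparameter search grid
(lr {1e-4,1e-3,1e-2,1e-1} x batch {16,32,64} x hidden {1,2,4,8,16,32,64});
the random search is scored by prediction strength with a desk-scale default
of 24 candidates (the full 360-candidate budget is a parameter away).

A deterministic lightweight clusterer — a Gaussian mixture on per-patient
score slopes, the sufficient statistic under the linear model — ships both as
a fast mode and as the independent oracle the VaDER partition is compared
against in tests.

### Number of subtypes

`select_k` chooses the smallest k in {2..5} whose *prediction strength*
(Tibshirani-Walther: split the patients in half, fit the clusterer on each
half, and take the minimum over test clusters of the preserved
co-membership fraction under the train-half assignment; empty test clusters
score 0) significantly exceeds a null distribution obtained by replacing the
train-half assignment with uniformly random labels of the same cluster sizes
(empirical p-value, default 0.05, both split orientations averaged).  If no k
is significant the report says "no subtype structure".

A calibration subtlety: with the *deterministic* slope-GMM clusterer this
random-label null is anti-conservative on one-component data, because both
halves lock onto the same dominant-variance axis of the blob and reproduce
each other far better than random labels do.  The stochastic VaDER clusterer
does not have this failure mode (on structureless data its mixture collapses
and the statistic is degenerate at 0), and the null is well calibrated — the
tests check super-uniformity of the p-values on one-component data.  For
this reason model selection defaults to the VaDER engine.

### Consensus and semantics

Final assignments aggregate 20 independently-seeded trainings: the consensus
matrix holds pairwise co-assignment frequencies and the final partition cuts
the average-linkage dendrogram of (1 - consensus) at k groups, which is
invariant to label permutations within runs.  For k=2 the cluster with the
larger mean composite slope (mean over outcomes of gamma_k + a1_ik) is named
*fast*, the other *slow*; exact ties break by cluster id and are flagged.
Trained models transfer to a second cohort by freezing the weights and
assigning that cohort's own progression scores (outcome set and grid must
match exactly).

## Subtype characterization

Per outcome and subtype, progression on the common timescale is modeled by a
mixed-effects model matched to the scale type: linear (statsmodels MixedLM,
random intercept + slope) for continuous scores; mixed-effects logistic for
binary items; cumulative-logit for ordinal items — the two GLMMs use a
per-patient 2-D Laplace approximation written for this package, since no
installed Python library fits ordinal/binary GLMMs with random slopes.
Ordinal outcomes with more than 10 observed levels fall back to the linear
model; this fallback is resolved once per outcome (not per subtype) so both
subtypes are always modeled on the same scale.  Inclusion filters: at least
30 patients with the outcome, at least 5 per subtype, at least 2 measurements
per patient.  The per-patient progression coefficient is the fixed slope plus
the patient's random-slope BLUP (posterior mode for the GLMMs); BLUP
shrinkage makes the within-group spread of these coefficients smaller than
the generating slope SD, which inflates standardized differences — they
quantify separation of the model-estimated progression rates, not of the raw
slopes.

Subtype contrasts are Hedges-corrected standardized mean differences,
signed (slow - fast)/pooled SD so that a faster fast subtype is *negative*.
Effects are pooled per symptom domain by a three-level random-effects
meta-analysis following the two-stage structure (outcomes within cohort,
then across cohorts): REML heterogeneity with a DerSimonian-Laird fallback,
and at the across-cohort level a Hartung-Knapp-style t-based standard error
and CI — with 3 cohorts, plain Wald intervals undercover badly, and the
t-adjustment keeps 95% coverage inside [0.90, 0.99] in simulation.  P-values
are corrected across domains by Benjamini-Hochberg; companion CIs are
re-computed at level 1 - alpha*r/m where r is the number of BH rejections
(the largest rejected step-up rank), an explicit, testable reading of
"CIs corrected for multiple testing".

Baseline associations fit a logistic model P(fast) ~ baseline value
(+ common-timescale disease duration as covariate), on the normalized scale;
the reported coefficient is sign-flipped so that negative values mean more
severe baseline symptoms associate with the fast subtype.  Complete
separation falls back to a ridge-stabilized fit and is flagged.  Survival is
compared by a Cox proportional-hazards model (lifelines; Efron ties) with
subtype, age and sex as covariates and the common timescale as time
variable.  Single-visit cross-sectional measurements (digital-gait style) are
compared by ANCOVA controlling for common-timescale duration, with the
F-test p-value for the group term.

## Subtype prediction and trial enrichment

Subtype membership is predicted from baseline values of the six predictor
outcomes (UPDRS I-III, PIGD, MoCA, SCOPA analogues; the UPDRS-IV analogue is
excluded because it is mostly not assessed at baseline) plus age and sex,
optionally adding the visit nearest one year (window 0.5-1.5 y; patients
without such a visit are excluded from that mode; missing entries are
median-imputed and flagged).  The model is an L2-penalized logistic
regression with inverse-prevalence class weights, evaluated by nested
repeated stratified cross-validation — 5 folds x 20 repeats in both loops by
default, with the inner loop selecting the penalty from
{0.01, 0.1, 1, 10, 100}; the examples and acceptance checks use fewer
repeats (stated per call) to keep runtimes in seconds.  Predicted
fast-subtype probabilities give the enrichment curve: for each threshold,
the fast fraction among selected patients against the still-eligible
fraction of all screened patients (our reading of the eligibility axis).

Sample sizes for a slope-difference trial come from the z-based Edland
closed form for a random-intercept-random-slope mixed model,

    n/arm = 2 (z_{1-a/2} + z_{pow})^2 (sigma_s^2 + sigma_e^2/Sxx) / Delta^2 ,

Sxx = sum_j (t_j - tbar)^2 over the visit schedule, Delta = effect x mean
slope, ceiled to an integer.  The default design is a one-year trial with
visits every 60 days (7 visits, 60/365.25-year spacing), two-tailed
alpha = 0.1, target power 80%, a 30% reduction of each treated patient's
progression rate, equal arms.  The Monte-Carlo validator simulates the
linear mixed model per replicate and analyzes it with the two-stage test
(per-patient OLS slope over the schedule, Welch two-sample test), which is
algebraically matched to the closed form's variance structure under this
balanced design; agreement is within ~2 power points at the Edland n, and
the empirical size at a zero effect is within Monte-Carlo error of alpha.

Enrichment to fast fraction p replaces the enrolled slope distribution by
the mixture: mean p*g_f + (1-p)*g_s, slope variance p*s_f^2 + (1-p)*s_s^2 +
p(1-p)(g_f - g_s)^2, so required n is non-increasing in p whenever
g_f > g_s; the treatment reduces each subtype's mean slope by the same
fraction (equivalently the mixture mean) at unchanged between-subject
variance — the alternative hypothesis the closed form is built on (a
per-patient multiplicative effect would also shrink the treated arm's
variance and make the simulator systematically exceed the analytic power).
The calibrated trial
components (slow 2, fast 6 UPDRS-I-III-sum points/year, between-subject
slope SD 2.5, residual SD 5, prevalence 0.25) are clinically plausible
magnitudes for a UPDRS-I-III-sum endpoint and give unenriched totals around
1300 patients at the default design.

## The synthetic-cohort generator

`generate_cohort` draws, per patient: a subtype (Bernoulli, default fast
fraction 0.25), a time shift (sigma_delta = 3 y), per-outcome bivariate
random effects, and linear latent trajectories on the normalized scale with
subtype-specific slopes (defaults: slow ~1-1.6 %/yr, fast ~2.2-3.6 %/yr per
outcome, within-subtype slope SD 0.4-0.6 %/yr — a slope separation of about
4 within-subtype SDs for the well-separated fixture).  Values map back to
raw scales (with direction flip for the MoCA analogue), are clipped to the
theoretical range (clipping, not truncated-normal resampling, mimics bounded
clinical scales transparently; the clipping rate is logged and stays below
1% at the default mid-stage baseline severities), and ordinal scales are
rounded to integers.  Visits are jittered around an annual schedule
(6 visits), 10% of entries are deleted completely at random (an optional
severity-dependent mechanism exists), and subtype affects only slopes by
default (baseline offsets behind a flag).  Subtype-linked mortality is
exponential (Weibull optional) with a fast-subtype log hazard ratio of
log 3.4 and administrative censoring.

What the generator deliberately does *not* emulate: non-linear trajectory
shapes, informative dropout, cross-outcome random-effect correlations,
treatment effects on observed scores, cohort-specific assessment batteries,
and floor/ceiling-heavy score distributions.  Passing tests therefore show
that the pipeline recovers the structure it assumes, at realistic noise
levels — not that real PD cohorts satisfy those assumptions.

Named fixtures: `well_separated` (n=200, the calibration workhorse),
`overlapping` (slope gap shrunk to ~1 within-SD), `null_one_subtype`
(single class; the negative control for model selection), and `tiny_worked`
(8 patients x 3 visits x 2 outcomes, noiseless, with hand-computable
expected values shipped alongside).

## Numerical choices and degenerate inputs

Variances are floored (1e-8 on latent variances, 1e-5 on residual SDs,
1e-4 on mixture variances) to keep precisions finite; log-variances in the
VAE are clipped to [-10, 10]; EM convergence tolerance 1e-8 relative;
empty selected sets truncate the enrichment curve (logged); a zero
cross-patient SD at the score origin drops the outcome (warned); zero pooled
SD makes an SMD undefined (raised); Cox with zero events raises; exact ties
in subtype naming break by cluster id (flagged).  Every randomized operation
accepts an explicit seed and derives child streams from it; identical seed
and configuration reproduce outputs bit-for-bit.

## Problem sizes used in tests and acceptance checks

Tests run the fixtures at their native sizes (n=200 cohorts, 20-run
consensus, 20-seed model-selection stability, 200-500 replicate
calibration simulations, 1000-2000 replicate trial simulations) — sizes
chosen so the whole suite completes in minutes on one CPU while leaving the
Monte-Carlo error well inside each asserted tolerance.

## Known limitations

Linear progression only; no joint modelling of dropout; diagonal
(per-outcome) random-effect structure by default; the Gibbs backend mixes
slowly in the residual/slope variances at short follow-up; the ordinal GLMM
uses a Laplace approximation that is first-order in the number of
measurements per patient; prediction-strength calibration is only guaranteed
for the stochastic clustering engine; sample-size formulas are z-based
(t-based refinements matter at very small n).
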