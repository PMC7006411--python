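# Methods

`dmtrank` implements a framework for personalized prediction of treatment
response in relapsing-remitting multiple sclerosis (RRMS): hierarchical
Bayesian outcome models over therapy cycles, a counterfactual per-patient
ranking of six disease-modifying therapies (DMTs), a validation suite, and
a propensity-weighted comparison of observed outcomes between patients who
did and did not receive their top-ranked therapy.  Because real multi-site
MS registry data cannot be redistributed, the package ships a synthetic
registry generator with known ground truth; every claim the test suite
makes is a claim about recovering that known truth.

## Unit of analysis and endpoints

The unit of observation is a *therapy cycle*: one continuous episode on an
index DMT (one of DMF, FTY, GA, IF, NA, TERI), with the patient's state at
the cycle start as predictors, the cycle duration in years as exposure, and
two endpoints observed on therapy — the number of relapses and the
occurrence of a confirmed disability progression (CDP).

CDP is detected on the EDSS trajectory: a worsening over the baseline EDSS
of at least 1.0 point when the baseline is 5.5 or lower and 0.5 point
otherwise, sustained for at least 91 days and confirmed by at least one
additional valid measurement at or above the progressed level taken 91 or
more days after onset.  An EDSS measurement is *valid* only if taken at
least 84 days after every preceding relapse (relapses transiently inflate
EDSS).  The baseline is the valid measurement closest to the cycle start
within a window from 183 days before to 91 days after the start.

Calendar phrases are fixed day constants used consistently everywhere:
3 months = 91 d, 6 months = 183 d, 12 months = 365 d.  Whether such rules
should use calendar months is genuinely ambiguous; fixed constants make
every decision reproducible bit-exactly.  Requiring the confirming
measurement to fall at least 91 days after onset (rather than merely after
it) is an interpretation: the confirmation is what demonstrates
sustainment.  The confirming measurement must itself pass the 84-day
post-relapse validity rule.

### Cohort filters

Quality filters (in order, counts itemized per criterion): complete
predictors; a documented pre-index relapse; a documented pre-index EDSS;
annualized relapse rate `n_relapses / index_duration` at most 12/year
(exactly 12 is kept — the exclusion is for rates strictly *above* 12).
Inclusion filters: age ≥ 18; baseline EDSS ≤ 6; index DMT among the six
studied; cycles started within 6 months of MS diagnosis without a previous
treatment failure are excluded, with "previous treatment failure"
operationalized as `dmts_count ≥ 1` (having taken at least one prior DMT);
then exactly one uniformly chosen cycle per patient (seeded); then clinical
sites with fewer than two remaining patients are dropped, iterated to a
fixed point.  The test split is by patient, `round(n_patients × fraction)`
patients in the test set.  All filters are idempotent and report removals
that sum exactly to the size change.

## Outcome models

Relapse counts follow a negative binomial with log link and exposure
offset,

    y_i ~ NB(mean = T_i · exp(x_i'β + u_{s(i)}),  shape = φ),

parameterized so the variance is `μ + μ²/φ`; CDP is Bernoulli on the logit
scale with the same offset,

    z_i ~ Bernoulli(logit⁻¹(x_i'γ + u_{s(i)} + log T_i)).

`u_s ~ Normal(0, σ²)` is a random intercept per clinical site, absorbing
between-site correlation.  The links (log / logit) are the conventional
GLM choices for these families.  Priors are weakly informative: Normal(0,
10) on the intercept, Normal(0, 2.5) on each fixed effect, Half-Cauchy(0,
5) on the NB shape (relapse model only), Gamma(1, 1) on the site standard
deviation; scales are standard deviations.  Continuous predictors are
standardized (training-set mean/SD, stored with the fit) before the
Normal(0, 2.5) prior is applied, since that prior scheme presumes
unit-scale inputs; categorical predictors are dummy-coded against the
alphabetically first level (DMF for both therapy factors, F for gender).

Three nested complexities share this structure and differ only in the
fixed-effect terms:

* **non-personalized** — index DMT only (5 dummies): every patient gets the
  same therapy ranking;
* **prognostic** — adds age, gender, baseline EDSS, the second-line
  indicator, current (previous) DMT and its duration plus their
  interaction, diagnosis distance, relapse distance, relapses count and
  DMTs count (26 columns): predictions are personalized but the *ranking*
  is not, because no patient characteristic interacts with the index DMT;
* **predictive** — adds index-DMT interactions with diagnosis distance,
  gender, relapses count and second-line (46 columns): the ranking itself
  becomes personal.

The term sets are strictly nested and the prognostic design is a column
prefix of the predictive one, so pinning the interaction coefficients to
zero reproduces prognostic predictions exactly (a tested invariant).

### Posterior computation

The log joint posterior (centered site intercepts; log-parameterized shape
and site SD with Jacobians) and its analytic gradient are implemented
directly.  Sampling uses affine-invariant ensemble MCMC (emcee): several
independent ensembles of `max(2·dim + 2, 48)` walkers, each initialized by
jittering (σ = 0.1) a MAP estimate found by L-BFGS with the analytic
gradient.  Two numerical choices matter:

* **centered parameterization** — every study condition here has many
  cycles per site, so the intercepts are strongly data-identified and the
  centered form mixes well; the non-centered form puts the posterior mass
  on a curved ridge (`site_sd · z_s ≈ const`) that stretch moves traverse
  poorly.
* **profile-style MAP initialization** — the joint mode of a centered
  hierarchy degenerates as `site_sd → 0`, so the site SD is never
  optimized jointly: coefficients and intercepts are optimized with the SD
  held at 1.0, the SD coordinate is then set to the empirical SD of the
  fitted intercepts (clipped to [0.05, 5]), and the rest is re-polished.

Per chain, `draws` states are kept from steps evenly spaced across the
post-warmup window.  Convergence is assessed with the rank-normalized
Gelman–Rubin statistic across ensembles via ArviZ; any parameter with
R-hat above the threshold (default 1.1) raises a diagnostic error naming
the offending parameters.  Defaults are 4 chains, 500 warmup + 250 kept
steps, 1000 draws per chain; tests and the acceptance script use 2 chains
and shorter windows (stated below).  Linear predictors are clipped at ±30
before exponentiation purely as an overflow guard.

### Prediction

Counterfactual prediction for therapy `d` rebuilds the design with every
cycle's index DMT (hence all its interaction columns) set to `d`, sets all
site intercepts to zero — a new patient gets identical predictions at
every site, an exactly tested invariant — and applies the offset
`log(duration)`.  Summaries per cycle are the posterior-predictive mean
outcome and the fraction of draws predicting absence of relapse / absence
of CDP; both are averaged analytically over each draw's sampling
distribution (`P(y=0) = (φ/(φ+μ))^φ` for the NB) rather than from sampled
outcomes, which removes simulation noise from summaries; sampled outcomes
remain available.  The per-cycle log predictive density is
`log mean_draws p(y_i | draw)`; validation reports its negative (NLL).

## Validation

Measures: MSE (posterior-mean count vs observed count; predicted
probability vs 0/1 CDP), total NLL, and Harrell's C-index over
duration-matched pairs — cycles are comparable when their durations differ
by at most 0.5 y if the shorter is under 0.5 y and at most 1.0 y otherwise;
among outcome-discordant pairs the event-bearing cycle should score higher,
ties credit 0.5.  The relapse concordance score is the posterior-mean
count; the CDP score is the predicted event probability.  Pairs are formed
within the evaluated prediction set.  Measures use only the prediction for
the cycle's observed index therapy.

Schemes: (i) k-fold cross-validation with patient-level folds, repeated
with fresh fold assignments to yield standard errors; per repeat each
cycle receives exactly one out-of-sample prediction (from the fold that
held it out) and one in-sample prediction (from one uniformly chosen other
fold's model, seeded); (ii) leave-one-site-out, predicting held-out sites
with zeroed intercepts; (iii) a held-out patient-level test set.
Calibration sorts cycles by predicted outcome into 20 equally populated
bins (stable sort; remainder to leading bins) and compares mean predicted
with mean observed outcome per bin.  Duration-stratified evaluation uses
right-closed windows (0, 0.5], (0.5, 1.5], …, (4.5, 5.5] years.
Non-convergent fold or site fits are dropped with a logged warning rather
than aborting the scheme.

## Therapy ranking and adherence comparison

For each cycle the six counterfactual summaries (mean predicted relapses,
or predicted CDP probability) are sorted ascending; the top-ranked therapy
DMT\* is the argmin, ties break alphabetically and are flagged when the
top-two gap falls below 1e-6 (the reported `second_margin` lets callers
apply stricter near-tie thresholds).  The ranking addresses a single
endpoint and is not an overall therapy recommendation.

Patients assigned the same DMT\* are split into receivers and
non-receivers.  Propensity scores for receiving DMT\* are estimated from
age, relapses count, categorized EDSS (0–1.5 / 2.0–3.5 / 4.0–6.0 by
default; the categorization is configurable since no canonical one is
fixed here) and diagnosis distance.  The default estimator is gradient
boosting with the stage chosen to minimize the mean absolute standardized
mean difference; the boosting is *cross-fitted* (each half-sample is
scored by a model trained on the other half) because in-sample propensities
drift toward the treatment indicator as stages accumulate, which fakes
balance while destroying the weights — cross-fitting removed the residual
confounding this left in pilot runs.  A logistic-regression estimator is
available and is used automatically below 40 observations per group.  ATE
weights (`1/e(x)` for receivers, `1/(1−e(x))` otherwise, normalized to
mean 1 within groups) reweight both groups toward the pooled population;
balance before/after and effective sample sizes are reported.

The weighted outcome comparison is a GLM of the observed outcome on the
receiver indicator with offset `log(duration)`: negative binomial for
relapses (overdispersion estimated by iterated Cameron–Trivedi auxiliary
regression), quasi-binomial (Pearson-scaled) for CDP, both with the
propensity weights as variance weights and HC1 sandwich covariance as the
design-based variance; p-values are Wald.  Levels with fewer than 10
observations in either group are excluded with an explicit reason.  A
negative slope means lower disease activity among receivers.

## Synthetic registry generator

`simulate.generate_registry` draws patient covariates with marginals chosen
as plausible for a treated RRMS population (age ≈ N(40, 11²) clipped to
[18, 75]; 70% female; baseline EDSS from a gamma shape rounded to the
half-point grid and clipped at 6; diagnosis distance ≈ 0.6 + Exp(5.5) y;
relapse distance ≈ 0.32 + Exp(0.6) y; relapses count 1 + Poisson(0.8);
DMTs count Poisson(1.2); index durations Gamma clipped to [0.3, 6] y),
assigns sites with Dirichlet-weighted sizes, draws site intercepts, and
generates outcomes from exactly the model laws above.  Default effect
sizes: intercepts log 0.35 (on-therapy annualized relapse rate ≈ 0.35) and
−2.4 (annual CDP odds ≈ 0.08); DMT effects spanning ±0.45 on the log-rate
scale with NA most effective; moderate covariate effects; dispersion 1.2;
site SD 0.25; all overridable.  True coefficients are expressed per design
column of the fitted models (continuous predictors standardized on the
generated sample), so parameter recovery compares like with like.  DMT
assignment is uniform-ish by default or covariate-dependent ("confounded":
sicker patients steered toward second-line therapies) for weighting tests.

The generator also emits EDSS trajectories and relapse dates consistent
with each cycle's endpoints (baseline measurement 5 days before the start;
progression placed early and confirmed when the CDP flag is set; relapses
placed where they cannot invalidate the relevant measurements), a labelled
trajectory suite for the CDP detector covering threshold, sustainment,
confirmation, validity and baseline-selection edge cases, and a two-group
adherence cohort in which receivers have exactly half the relapse rate of
non-receivers, optionally with planted confounding acting through the
covariates the propensity model observes.

What the generator does **not** emulate: the joint covariate distribution
of any real registry, informative visit schedules, missingness, diagnosis
drift, therapy switching within a cycle, or secular trends.  Passing tests
therefore demonstrate that the machinery recovers known structure under
the model's own assumptions — not that the models are well specified for
real registry data.

## Problem sizes used by tests and the acceptance script

Simulation sizes were set so the whole suite runs comfortably on one CPU:
parameter recovery uses 20 replicates (10 in the acceptance script) of
2000 cycles over 20 sites with 2 chains × (400 warmup + 200 kept) steps;
the nested-model comparison uses 10 seeds (5 in the script) of 1400 cycles
with a 30% test split; ranking stability uses 1200 cycles over 10 sites;
the adherence comparison uses 4000 cycles and 5 confounded seeds; the
no-overfitting limit scores the generator's true model, which needs no
MCMC.  Recovery checks are bias checks: posterior means are averaged over
replicates before comparison with truth, and 95% interval coverage is
pooled over replicates and coefficients.

## Known limitations

* The ensemble sampler yields modest effective sample sizes per draw
  compared with gradient-based samplers; posterior means and intervals at
  the tested sizes are accurate (coverage ≈ 95%), but tail quantiles of
  high-dimensional fits should not be over-interpreted at short chain
  settings.
* The current-therapy block (`current_dmt`, its duration and their
  interaction) is nearly collinear by construction — the "NONE" level has
  constant duration 0 — so individual coefficients in that block are only
  jointly identified; predictions are unaffected, and recovery tests
  average over replicates for this reason.
* Discretization of continuous predictors (sometimes used in registry
  practice) is not implemented; predictors enter continuously and
  standardized.
* The adherence comparison estimates a weighted association under
  no-unmeasured-confounding; no doubly robust or matching estimators are
  provided.
* `svyglm`-style survey variance is approximated by HC1 sandwich errors
  with variance weights; finite-population corrections are out of scope.
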